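"""Off-axis interference synthesis and Fourier-sideband demodulation.

The digital Mach-Zehnder: for each irradiation polarization s in {0, 90}
degrees the object field is the matching column of the Jones matrix field;
a tilted plane-wave reference at 45 degrees (amplitude r/sqrt(2) in each
analyzer channel) writes a spatial carrier onto the recorded intensity.
Four channels (s x analyzer) are recorded; a single 2D FFT per channel
isolates the cross-term sideband, which after baseband shift and reference
normalisation returns the complex object amplitude, i.e. one element of the
Jones matrix per Eq.-style channel assignment:

    w11 <- (s=0,  A=0)    w21 <- (s=0,  A=90)
    w12 <- (s=90, A=0)    w22 <- (s=90, A=90)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "InterferogramSet",
    "RecoveredField",
    "DemodulationError",
    "synthesize",
    "demodulate",
    "rephase",
    "estimate_carrier",
]

#: pixels excluded from the validity mask at each image border after demodulation
BORDER = 16

CHANNELS = ((0, 0), (0, 90), (90, 0), (90, 90))


class DemodulationError(RuntimeError):
    """No usable carrier sideband in the recorded interferograms."""


@dataclass
class InterferogramSet:
    """Four off-axis intensity recordings with carrier metadata.

    ``images[(s, analyzer)]`` are non-negative real images (quantized
    integers when ``bit_depth`` is set, with ``scale`` intensity units per
    digital number).  Carrier components are in cycles/pixel along the
    (row, column) axes.
    """

    images: dict[tuple[int, int], np.ndarray]
    carrier: tuple[float, float] | None
    reference_amplitude: float
    wavelength_um: float = 0.6328
    bit_depth: int | None = 16
    scale: float = 1.0

    def __post_init__(self) -> None:
        if set(self.images) != set(CHANNELS):
            raise ValueError(f"need the four channels {CHANNELS}")
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) != 1:
            raise ValueError("channel image shapes differ")
        for ch, im in self.images.items():
            if np.any(np.asarray(im) < 0):
                raise ValueError(f"negative intensity in channel {ch}")
        if self.carrier is not None:
            for c in self.carrier:
                if not (0.0 < abs(c) < 0.5):
                    raise ValueError("carrier components must be in (0, 0.5) cycles/pixel")

    @property
    def grid(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    def intensity(self, channel: tuple[int, int]) -> np.ndarray:
        """Channel intensity in physical units (undoes quantization scale)."""
        im = np.asarray(self.images[channel], dtype=float)
        return im * self.scale if self.bit_depth else im


@dataclass
class RecoveredField:
    """Complex Jones matrix field recovered from the four channels."""

    w: np.ndarray  # (A, B, 2, 2) complex
    mask: np.ndarray  # (A, B) bool validity
    carrier: tuple[float, float] | None = None
    piston_reference: float | None = None
    phase_plane: str | float = "integral"

    def __post_init__(self) -> None:
        if self.w.shape[:-2] != self.mask.shape or self.w.shape[-2:] != (2, 2):
            raise ValueError("w and mask shapes inconsistent")

    def copy(self) -> "RecoveredField":
        return replace(self, w=self.w.copy(), mask=self.mask.copy())


def _carrier_phase(shape: tuple[int, int], carrier: tuple[float, float]) -> np.ndarray:
    a = np.arange(shape[0])[:, None]
    b = np.arange(shape[1])[None, :]
    return np.exp(2j * np.pi * (carrier[0] * a + carrier[1] * b))


def synthesize(
    jones: np.ndarray,
    carrier: tuple[float, float] = (0.2, 0.2),
    reference_amplitude: float = 2.0,
    noise_sd: float = 0.0,
    bit_depth: int | None = 16,
    seed: int = 0,
) -> InterferogramSet:
    """Record the four off-axis interference channels of a Jones field.

    The reference is a tilted plane wave linearly polarized at 45 degrees,
    so both analyzer channels beat against the amplitude ``r / sqrt(2)``.
    ``noise_sd`` is the additive Gaussian detector noise, in the same
    intensity units as the fringes; quantization (if any) maps the maximum
    intensity over the four channels to full scale.
    """
    jones = np.asarray(jones)
    if jones.ndim != 4 or jones.shape[-2:] != (2, 2):
        raise ValueError("expected an (A, B, 2, 2) Jones field")
    for c in carrier:
        if not (0.0 < abs(c) < 0.5):
            raise ValueError("carrier must be within (0, 0.5) cycles/pixel (Nyquist)")
    shape = jones.shape[:2]
    ref = (reference_amplitude / np.sqrt(2.0)) * _carrier_phase(shape, carrier)
    rng = np.random.default_rng(seed)

    raw: dict[tuple[int, int], np.ndarray] = {}
    for s, omega in CHANNELS:
        comp = jones[..., omega // 90, s // 90]  # <E_s, analyzer omega>
        I = np.abs(comp + ref) ** 2
        if noise_sd > 0:
            I = I + rng.normal(0.0, noise_sd, size=shape)
        raw[(s, omega)] = np.clip(I, 0.0, None)

    scale = 1.0
    if bit_depth is not None:
        full = max(float(im.max()) for im in raw.values())
        levels = 2**bit_depth - 1
        scale = (full / levels) if full > 0 else 1.0
        dtype = np.uint8 if bit_depth <= 8 else np.uint16
        raw = {ch: np.round(im / scale).astype(dtype) for ch, im in raw.items()}

    return InterferogramSet(
        images=raw,
        carrier=carrier,
        reference_amplitude=reference_amplitude,
        bit_depth=bit_depth,
        scale=scale,
    )


def estimate_carrier(intensity: np.ndarray) -> tuple[float, float]:
    """Locate the strongest non-DC spectral peak (row-frequency > 0 half-plane)."""
    F = np.fft.fft2(intensity)
    fu = np.fft.fftfreq(intensity.shape[0])[:, None]
    fv = np.fft.fftfreq(intensity.shape[1])[None, :]
    mag = np.abs(F)
    mag[(np.abs(fu) < 0.05) & (np.abs(fv) < 0.05)] = 0.0  # DC hump
    mag[fu.ravel() < 0, :] = 0.0  # keep one sideband
    if mag.max() <= 0:
        raise DemodulationError("no spectral peak outside the DC term")
    idx = np.unravel_index(int(np.argmax(mag)), mag.shape)
    return float(fu[idx[0], 0]), float(fv[0, idx[1]])


def _demodulate_channel(
    intensity: np.ndarray,
    carrier: tuple[float, float],
    window_halfwidth: float,
    window: np.ndarray | None,
) -> np.ndarray:
    if window is not None:
        intensity = intensity * window
    F = np.fft.fft2(intensity)
    fu = np.fft.fftfreq(intensity.shape[0])[:, None]
    fv = np.fft.fftfreq(intensity.shape[1])[None, :]
    keep = (np.abs(fu - carrier[0]) <= window_halfwidth) & (np.abs(fv - carrier[1]) <= window_halfwidth)
    side = np.fft.ifft2(F * keep)
    side = side * np.conj(_carrier_phase(intensity.shape, carrier))
    # the +carrier sideband carries conj(object) * reference
    return np.conj(side)


def demodulate(
    igs: InterferogramSet,
    window_halfwidth: float = 0.1,
    apodize: bool = True,
) -> RecoveredField:
    """Recover the complex Jones matrix field from the four channels.

    Per channel: (Hann-apodized) 2D FFT, square sideband window centred on
    the carrier, inverse FFT, exact baseband shift, conjugation, division by
    the reference amplitude and (where used) the apodization window.  A
    16-pixel border and near-zero window weights are masked out.  With no
    carrier metadata the carrier is estimated from the strongest non-DC
    spectral peak of the first channel.
    """
    if igs.carrier is None:
        igs = replace(igs, carrier=estimate_carrier(igs.intensity((0, 0))))
    u0, v0 = igs.carrier
    if min(abs(u0), abs(v0)) <= window_halfwidth:
        import warnings

        warnings.warn("sideband window overlaps the DC term; expect leakage", stacklevel=2)
    shape = igs.grid
    total_power = sum(float(np.sum(igs.intensity(ch) ** 2)) for ch in CHANNELS)
    if total_power <= 0:
        raise DemodulationError("all-zero interferograms: no carrier to demodulate")

    window = None
    if apodize:
        window = np.outer(np.hanning(shape[0]), np.hanning(shape[1]))

    r_chan = igs.reference_amplitude / np.sqrt(2.0)
    w = np.empty(shape + (2, 2), dtype=complex)
    mask = np.ones(shape, dtype=bool)
    for s, omega in CHANNELS:
        field_c = _demodulate_channel(igs.intensity((s, omega)), igs.carrier, window_halfwidth, window)
        if window is not None:
            ok = window > 0.05
            field_c = np.where(ok, field_c / np.where(ok, window, 1.0), 0.0)
            mask &= ok
        w[..., omega // 90, s // 90] = field_c / r_chan

    if BORDER > 0:
        mask[:BORDER, :] = False
        mask[-BORDER:, :] = False
        mask[:, :BORDER] = False
        mask[:, -BORDER:] = False
    return RecoveredField(w=w, mask=mask, carrier=igs.carrier)


def rephase(rec: RecoveredField, anchor: str = "det") -> RecoveredField:
    """Remove the global piston phase under a fixed convention.

    ``anchor="det"`` (default): the piston is half the argument of the
    masked mean determinant — exact for unimodular Jones fields, with the
    pi ambiguity resolved by requiring ``Re(mean w11) > 0``.
    ``anchor="w11"``: set the mean phase of w11 over the mask to zero.
    Idempotent; invariant to any global phase applied before recording.
    """
    if not np.any(rec.mask):
        raise ValueError("empty validity mask")
    w = rec.w
    m = rec.mask
    if anchor == "det":
        det = w[..., 0, 0] * w[..., 1, 1] - w[..., 0, 1] * w[..., 1, 0]
        chi = 0.5 * float(np.angle(det[m].mean()))
        if float(np.real(np.mean(w[..., 0, 0][m] * np.exp(-1j * chi)))) < 0:
            chi += np.pi
    elif anchor == "w11":
        chi = float(np.angle(w[..., 0, 0][m].mean()))
    else:
        raise ValueError(f"unknown piston anchor {anchor!r}")
    out = rec.copy()
    out.w = w * np.exp(-1j * chi)
    out.piston_reference = chi
    return out
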