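"""Pixelwise anisotropy maps (theziograms) from a recovered Jones field.

A theziogram is the map of one aggregate anisotropy parameter — linear
birefringence (LB), circular birefringence (CB), linear dichroism (LD) or
circular dichroism (CD) — reconstructed per pixel from the 2x2 complex
Jones matrix field, either by the trace/arccos closed form (``method
"closed_form"``, exact for phase-only anisotropy) or by the principal matrix
logarithm (``method "exact"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anisotropy import invert_exact, invert_closed_form
from .interferometry import RecoveredField

__all__ = ["Theziogram", "QualityError", "PARAMETERS", "theziogram_maps", "histogram"]

PARAMETERS = ("LB", "CB", "LD", "CD")


class QualityError(RuntimeError):
    """More than half of the masked pixels were singular under inversion."""


@dataclass
class Theziogram:
    """One reconstructed anisotropy map with its validity bookkeeping."""

    values: np.ndarray
    parameter: str
    mask: np.ndarray
    phase_plane: str | float = "integral"
    convention: str = "eq10_11"
    method: str = "exact"
    dropped_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"parameter must be one of {PARAMETERS}")
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")

    @property
    def k(self) -> int:
        """Number of valid pixels entering the statistics."""
        return int(np.count_nonzero(self.mask))

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def theziogram_maps(
    rec: RecoveredField,
    method: str = "exact",
    convention: str = "eq10_11",
    clip_arccos: bool = False,
) -> dict[str, Theziogram]:
    """Reconstruct the four anisotropy maps from a (possibly gated) field.

    Singular pixels (arccos out of domain, branch point of the logarithm)
    are dropped from the mask, not clamped; the dropped fraction is carried
    on each map and a :class:`QualityError` is raised if it exceeds one half.
    """
    if not np.any(rec.mask):
        raise ValueError("empty validity mask")
    if method == "closed_form":
        agg = invert_closed_form(rec.w, convention=convention, clip_arccos=clip_arccos, raise_on_domain=False)
    elif method == "exact":
        _, agg = invert_exact(rec.w, raise_on_domain=False)
    else:
        raise ValueError(f"unknown inversion method {method!r}")

    mask = rec.mask & agg.valid
    n_in = int(np.count_nonzero(rec.mask))
    dropped = 1.0 - int(np.count_nonzero(mask)) / n_in
    if dropped > 0.5:
        raise QualityError(f"{dropped:.0%} of masked pixels singular under inversion")

    out: dict[str, Theziogram] = {}
    for name in PARAMETERS:
        vals = np.real(agg.by_name(name)).astype(float)
        out[name] = Theziogram(
            values=np.where(mask, vals, 0.0),
            parameter=name,
            mask=mask,
            phase_plane=rec.phase_plane,
            convention=convention,
            method=method,
            dropped_fraction=dropped,
        )
    return out


def histogram(tz: Theziogram, n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Probability histogram of a theziogram over its valid pixels.

    Returns ``(bin_edges, probabilities)`` with probabilities summing to 1;
    the range is [min, max] over the mask.
    """
    vals = tz.masked_values()
    if vals.size == 0:
        raise ValueError("empty validity mask")
    if vals.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} pixels, have {vals.size}")
    counts, edges = np.histogram(vals, bins=n_bins)
    return edges, counts / counts.sum()
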