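"""Algebra of complex optical anisotropy for non-depolarizing media.

A thin polycrystalline domain with linear birefringence (two bases),
circular birefringence, and the matching dichroisms is described by a
traceless generator ``G`` whose matrix exponential ``W = exp(G / 2)`` is the
generalized 2x2 complex Jones matrix.  Because ``G**2 = -Q**2 * I`` (with
``Q`` the complex modulus of the anisotropy vector) the exponential closes
into ``W = cos(Q/2) I + sin(Q/2)/Q * G``, and the inverse problem reduces to
a principal matrix logarithm of a unimodular matrix.

Conventions
-----------
* complex linear components ``B = LB - i * LD`` (per basis), circular
  component ``A = CB - i * CD``;
* ``Q = sqrt(B_0_90**2 + B_45_135**2 + A**2)`` on the principal square-root
  branch (``Re Q >= 0``, and ``Im Q >= 0`` on the cut);
* all angles in radians; dichroism is a radian-equivalent attenuation.

Everything here is vectorised: the six state components may be scalars or
arrays of a common broadcast shape, and Jones matrices are ``(..., 2, 2)``
complex arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "AnisotropyState",
    "AggregateInversion",
    "SingularBranchError",
    "ArccosDomainError",
    "q_modulus",
    "jones_forward",
    "invert_closed_form",
    "invert_exact",
    "stack_product",
]

#: |Q| below which the removable singularities sin(Q/2)/Q and Q/(2 sin(Q/2))
#: are evaluated by their 6th-order series.
_SERIES_CUTOFF = 1e-6


class SingularBranchError(ValueError):
    """Raised when sin(Q/2) vanishes away from Q=0 (branch point Q = 2*pi)."""


class ArccosDomainError(ValueError):
    """Raised when the arccos argument of the trace inversion leaves [-1, 1]."""


@dataclass(frozen=True)
class AnisotropyState:
    """Six anisotropy parameters of one pixel or a field of pixels.

    Parameters are the linear birefringence in the 0-90 and 45-135 degree
    bases, circular birefringence, and the three matching dichroisms.  Each
    may be a float or an ndarray; shapes must broadcast.
    """

    lb_0_90: np.ndarray | float = 0.0
    lb_45_135: np.ndarray | float = 0.0
    cb: np.ndarray | float = 0.0
    ld_0_90: np.ndarray | float = 0.0
    ld_45_135: np.ndarray | float = 0.0
    cd: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = np.asarray(getattr(self, f.name))
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite value in {f.name}")

    # -- complex components -------------------------------------------------
    @property
    def b_0_90(self) -> np.ndarray:
        return np.asarray(self.lb_0_90) - 1j * np.asarray(self.ld_0_90)

    @property
    def b_45_135(self) -> np.ndarray:
        return np.asarray(self.lb_45_135) - 1j * np.asarray(self.ld_45_135)

    @property
    def a_circ(self) -> np.ndarray:
        return np.asarray(self.cb) - 1j * np.asarray(self.cd)

    # -- aggregates ---------------------------------------------------------
    @property
    def lb(self) -> np.ndarray:
        """Aggregate linear birefringence, root-sum-square of the two bases."""
        return np.hypot(np.asarray(self.lb_0_90, float), np.asarray(self.lb_45_135, float))

    @property
    def ld(self) -> np.ndarray:
        """Aggregate linear dichroism."""
        return np.hypot(np.asarray(self.ld_0_90, float), np.asarray(self.ld_45_135, float))

    @property
    def q_complex(self) -> np.ndarray:
        """Complex anisotropy-vector modulus, principal square-root branch."""
        q2 = self.b_0_90**2 + self.b_45_135**2 + self.a_circ**2
        return np.sqrt(q2.astype(complex))

    @property
    def q_abs(self) -> np.ndarray:
        return q_modulus(self)

    def broadcast_shape(self) -> tuple[int, ...]:
        return np.broadcast_shapes(*(np.shape(getattr(self, f.name)) for f in fields(self)))

    def add(self, other: "AnisotropyState") -> "AnisotropyState":
        """Componentwise sum (thin-element superposition within one layer)."""
        return AnisotropyState(
            *(np.asarray(getattr(self, f.name)) + np.asarray(getattr(other, f.name)) for f in fields(self))
        )


def q_modulus(state: AnisotropyState) -> np.ndarray | float:
    """Real modulus of the generalized anisotropy vector.

    ``sqrt(LB_0_90^2 + LB_45_135^2 + CB^2 + LD_0_90^2 + LD_45_135^2 + CD^2)``,
    equal to ``sqrt(LB^2 + CB^2 + LD^2 + CD^2)`` with the aggregate LB and LD.
    """
    comps = [state.lb_0_90, state.lb_45_135, state.cb, state.ld_0_90, state.ld_45_135, state.cd]
    out = np.sqrt(sum(np.asarray(c, float) ** 2 for c in comps))
    return float(out) if out.ndim == 0 else out


def _sin_half_over_q(q: np.ndarray) -> np.ndarray:
    """sin(Q/2)/Q with its removable singularity handled by a series."""
    q = np.asarray(q)
    small = np.abs(q) < _SERIES_CUTOFF
    safe = np.where(small, 1.0, q)
    out = np.sin(safe / 2.0) / safe
    series = 0.5 * (1.0 - q * q / 24.0 + q**4 / 1920.0)
    return np.where(small, series, out)


def _q_over_2sin_half(q: np.ndarray) -> np.ndarray:
    """Q/(2 sin(Q/2)) with its removable singularity handled by a series."""
    q = np.asarray(q)
    small = np.abs(q) < _SERIES_CUTOFF
    safe = np.where(small, 1.0, q)
    out = safe / (2.0 * np.sin(safe / 2.0))
    series = 1.0 + q * q / 24.0 + 7.0 * q**4 / 5760.0
    return np.where(small, series, out)


def generator(state: AnisotropyState) -> np.ndarray:
    """Traceless generator ``G`` of the Jones matrix, shape (..., 2, 2)."""
    b0 = state.b_0_90
    b45 = state.b_45_135
    a = state.a_circ
    shape = np.broadcast_shapes(np.shape(b0), np.shape(b45), np.shape(a))
    G = np.empty(shape + (2, 2), dtype=complex)
    G[..., 0, 0] = -1j * b0
    G[..., 0, 1] = a - 1j * b45
    G[..., 1, 0] = -a - 1j * b45
    G[..., 1, 1] = 1j * b0
    return G


def jones_forward(state: AnisotropyState) -> np.ndarray:
    """Generalized Jones matrix of a thin layer with complex anisotropy.

    ``W = cos(Q/2) I + sin(Q/2)/Q * G``; equals ``expm(G / 2)`` exactly since
    the generator squares to ``-Q**2 I``.  Always unimodular; unitary iff all
    dichroisms vanish.
    """
    q = state.q_complex
    c = np.cos(q / 2.0)
    s = _sin_half_over_q(q)
    G = generator(state)
    W = np.zeros_like(G)
    W[..., 0, 0] = c + s * G[..., 0, 0]
    W[..., 0, 1] = s * G[..., 0, 1]
    W[..., 1, 0] = s * G[..., 1, 0]
    W[..., 1, 1] = c + s * G[..., 1, 1]
    return W


@dataclass(frozen=True)
class AggregateInversion:
    """Aggregate anisotropy recovered from a Jones matrix field.

    ``lb``/``ld`` are root-sum-square aggregates over the two linear bases
    (non-negative); ``cb``/``cd`` are signed.  ``valid`` marks pixels where
    the inversion is well posed (arccos in domain, away from the Q = 2*pi
    branch point).
    """

    q: np.ndarray
    lb: np.ndarray
    cb: np.ndarray
    ld: np.ndarray
    cd: np.ndarray
    valid: np.ndarray

    def by_name(self, name: str) -> np.ndarray:
        return {"LB": self.lb, "CB": self.cb, "LD": self.ld, "CD": self.cd}[name]


def _check_matrix(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W)
    if W.shape[-2:] != (2, 2):
        raise ValueError(f"expected (..., 2, 2) Jones matrices, got shape {W.shape}")
    return W


def invert_closed_form(
    W: np.ndarray,
    convention: str = "eq10_11",
    clip_arccos: bool = False,
    raise_on_domain: bool | None = None,
) -> AggregateInversion:
    """Trace/real-part inversion of a Jones matrix to aggregate anisotropy.

    ``Q = 2 arccos(0.5 (Re w11 + Re w22))`` followed by linear combinations
    of the matrix elements scaled by ``Q / (2 sin(Q/2))``.  Exact for pure
    phase anisotropy; a weak-dichroism approximation otherwise (the complex
    Q is replaced by its real trace estimate).

    convention
        ``"eq10_11"`` (default): linear birefringence from imaginary parts,
        linear dichroism from real parts, circular birefringence from
        ``Re(w12 - w21)`` and circular dichroism from ``-Im(w12 - w21)`` —
        the assignment consistent with the forward model (see package docs
        on the Re/Im labelling ambiguity).  ``"eq15"`` swaps the
        birefringence/dichroism roles of the real and imaginary parts.
    clip_arccos
        Clip the arccos argument into [-1, 1] instead of masking such pixels
        out (demodulation noise can push it slightly out of domain).
    raise_on_domain
        If True, raise :class:`ArccosDomainError` / :class:`SingularBranchError`
        on any bad pixel instead of masking.  Defaults to True for scalar
        (0-d) input, False for fields.
    """
    W = _check_matrix(W)
    if convention not in ("eq10_11", "eq15"):
        raise ValueError(f"unknown inversion convention {convention!r}")
    scalar = W.ndim == 2
    if raise_on_domain is None:
        raise_on_domain = scalar

    t = 0.5 * (W[..., 0, 0].real + W[..., 1, 1].real)
    in_domain = np.abs(t) <= 1.0
    if clip_arccos:
        t = np.clip(t, -1.0, 1.0)
        in_domain = np.ones_like(in_domain)
    elif raise_on_domain and not np.all(in_domain):
        raise ArccosDomainError("trace/2 outside [-1, 1]; strongly dichroic matrix")
    q = 2.0 * np.arccos(np.clip(t, -1.0, 1.0))

    sin_half = np.sin(q / 2.0)
    # q -> 0 is removable (handled by the series); q -> 2*pi is a true branch point
    singular = (np.abs(sin_half) < 1e-12) & (np.abs(q) > 1.0)
    if raise_on_domain and np.any(singular & in_domain):
        raise SingularBranchError("sin(Q/2) = 0 at Q = 2*pi; branch point")
    pref = _q_over_2sin_half(np.where(singular, 1.0, q))

    im = W.imag
    re = W.real
    d_im = np.hypot(im[..., 1, 1] - im[..., 0, 0], im[..., 0, 1] + im[..., 1, 0])
    d_re = np.hypot(re[..., 1, 1] - re[..., 0, 0], re[..., 0, 1] + re[..., 1, 0])
    c_re = re[..., 0, 1] - re[..., 1, 0]
    c_im = im[..., 0, 1] - im[..., 1, 0]

    if convention == "eq10_11":
        lb, ld = pref * d_im, pref * d_re
        cb, cd = pref * c_re, -pref * c_im
    else:  # eq15: birefringence from real parts, dichroism from imaginary
        lb, ld = pref * d_re, pref * d_im
        cb, cd = -pref * c_im, pref * c_re

    valid = in_domain & ~singular
    return AggregateInversion(q=q, lb=lb, cb=cb, ld=ld, cd=cd, valid=valid)


def invert_exact(W: np.ndarray, raise_on_domain: bool | None = None) -> tuple[AnisotropyState, AggregateInversion]:
    """Exact inversion via the principal matrix logarithm.

    For unimodular ``W``: ``Q = 2 arccos_complex(tr W / 2)`` (principal
    branch, ``Re Q`` in ``[0, 2*pi]``), ``G = (W - cos(Q/2) I) * Q/sin(Q/2)``,
    and the six anisotropy parameters are read off the generator.  Exact
    round trip of :func:`jones_forward` for ``Re Q`` inside ``(0, 2*pi)``
    (endpoints are branch points).

    Returns the full six-component state and the aggregate view.
    """
    W = _check_matrix(W)
    scalar = W.ndim == 2
    if raise_on_domain is None:
        raise_on_domain = scalar

    tr2 = 0.5 * (W[..., 0, 0] + W[..., 1, 1]).astype(complex)
    q = 2.0 * np.arccos(tr2)
    # match the principal square-root cut used by the forward model:
    # Re q >= 0 always (arccos range); on Re q == 0 take Im q >= 0
    flip = (np.abs(q.real) < 1e-12) & (q.imag < 0)
    q = np.where(flip, -q, q)

    sin_half = np.sin(q / 2.0)
    singular = (np.abs(sin_half) < 1e-12) & (np.abs(q) > 1.0)
    out_of_range = np.abs(q.real) > 2.0 * np.pi - 1e-9
    bad = singular | out_of_range
    if raise_on_domain and np.any(bad):
        raise SingularBranchError("|Re Q| >= 2*pi: principal log branch ambiguity")

    inv_s = 1.0 / _sin_half_over_q(np.where(bad, 1.0, q))
    c = np.cos(q / 2.0)
    G11 = (W[..., 0, 0] - c) * inv_s
    G12 = W[..., 0, 1] * inv_s
    G21 = W[..., 1, 0] * inv_s

    b0 = 1j * G11
    b45 = 0.5j * (G12 + G21)
    a = 0.5 * (G12 - G21)

    state = AnisotropyState(
        lb_0_90=b0.real,
        lb_45_135=b45.real,
        cb=a.real,
        ld_0_90=-b0.imag,
        ld_45_135=-b45.imag,
        cd=-a.imag,
    )
    agg = AggregateInversion(
        q=q,
        lb=np.hypot(b0.real, b45.real),
        cb=a.real,
        ld=np.hypot(b0.imag, b45.imag),
        cd=-a.imag,
        valid=~bad,
    )
    return state, agg


def stack_product(layers: list[np.ndarray] | tuple[np.ndarray, ...]) -> np.ndarray:
    """Pixelwise ordered product of layer Jones fields.

    ``layers[0]`` is encountered first by the beam, so the composite is
    ``W_L @ ... @ W_2 @ W_1`` at every pixel.
    """
    if len(layers) == 0:
        raise ValueError("empty layer stack")
    layers = [_check_matrix(L) for L in layers]
    shape = layers[0].shape
    for L in layers[1:]:
        if L.shape != shape:
            raise ValueError(f"layer grid mismatch: {L.shape} vs {shape}")
    out = layers[0]
    for L in layers[1:]:
        out = np.matmul(L, out)
    return out
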