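"""Seeded synthetic facies phantoms: per-pixel anisotropy fields and cohorts.

A dehydrated biofluid film ("facies") organises into concentric zones: an
edge ring rich in needle-like protein crystals (a dendritic network carrying
linear birefringence/dichroism) and a central region rich in spherulites
(radially organised domains carrying circular birefringence/dichroism).
The generator rasterises such structures into six per-pixel anisotropy
planes, composes layers through the Jones calculus, and derives seeded
two-group cohorts (healthy-like vs pathology-like).

The pathology-like deltas emulate the qualitative picture reported for
cancer-related changes of blood films: needle orientation ranges narrow
(crystallisation becomes directionally ordered), needle density grows, and
circular anisotropy (spherulite concentration and optical activity) rises.
No claim of clinical realism is made — parameters are stated defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line_aa

from .anisotropy import AnisotropyState, jones_forward, stack_product

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "Sample",
    "draw_orientations",
    "render_layer",
    "render_jones_field",
    "make_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Stated world of one synthetic facies.

    Zones are concentric radius fractions ``(central, transitional, 1.0)``:
    needles populate the transitional+edge annulus, spherulites the
    central+transitional disc.  ``smooth_sigma`` (px) is the optical
    point-spread blur applied to all six planes; it also band-limits the
    object so the off-axis sideband window can hold its spectrum.
    """

    grid: tuple[int, int] = (1120, 960)
    zones: tuple[float, float, float] = (0.45, 0.75, 1.0)
    # dendritic (needle) network
    n_needles: int = 299
    needle_length: tuple[float, float] = (76.8, 211.2)  # px
    needle_width: tuple[float, float] = (3.0, 6.0)  # px
    gamma_range: tuple[float, float] = (0.0, 2.0 * math.pi)
    gamma_kappa: float | None = None  # None = uniform on gamma_range
    delta_mean: float = 1.5  # rad
    delta_sd: float = 0.7
    dichroism_fraction: float = 0.2
    # spherulite network
    n_spherulites: int = 535
    spherulite_radius: tuple[float, float] = (5.0, 11.0)  # px
    cb_mean: float = 1.2  # rad
    cb_sd: float = 0.4
    cd_fraction: float = 0.2
    # stacking and optics
    n_layers: int = 4
    smooth_sigma: float = 3.0  # px
    seed: int = 7

    def __post_init__(self) -> None:
        if min(self.grid) < 8:
            raise ValueError("degenerate grid")
        z = self.zones
        if not (0.0 < z[0] < z[1] <= z[2] <= 1.0):
            raise ValueError("zone radius fractions must be strictly increasing in (0, 1]")
        if not (self.gamma_range[0] < self.gamma_range[1]):
            raise ValueError("gamma_min must be < gamma_max")
        for name in ("delta_mean", "delta_sd", "dichroism_fraction", "cb_mean", "cb_sd", "cd_fraction", "smooth_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")

    @classmethod
    def default(cls, grid: tuple[int, int] = (1120, 960), **overrides) -> "PhantomSpec":
        """Default spec with structure counts/lengths scaled to the grid.

        Needle lengths scale with the linear grid size; needle widths,
        spherulite radii and the optical blur are resolution-scale constants
        in pixels.  Counts are set from fixed coverage targets (~0.3 of the
        area per layer for needles, ~0.2 for spherulites).
        """
        a, b = grid
        lin = min(a, b)
        length = (0.08 * lin, 0.22 * lin)
        width = (3.0, 6.0)
        mean_needle_area = (length[0] + length[1]) / 2 * (width[0] + width[1]) / 2
        n_needles = max(3, round(0.18 * a * b / mean_needle_area))
        radius = (5.0, 11.0)
        mean_disc_area = math.pi * ((radius[0] + radius[1]) / 2) ** 2
        n_spherulites = max(2, round(0.10 * a * b / mean_disc_area))
        kwargs = dict(
            grid=grid,
            n_needles=n_needles,
            needle_length=length,
            needle_width=width,
            n_spherulites=n_spherulites,
            spherulite_radius=radius,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def pathology_like(self) -> "PhantomSpec":
        """Pathology-like counterpart of this spec.

        Dendrites coarsen into oriented bundles: the needle orientation
        range narrows to ``[0, pi/4]`` and growth concentrates into fewer,
        longer needles (0.6x count, 1.3x length — less of the film is
        covered, so the linear-anisotropy map becomes sparser and more
        heavy-tailed).  Chiral domains proliferate and strengthen while
        their amplitude dispersion narrows (2x spherulite count, 1.5x
        optical activity, 0.5x spread — the "range of changes" of the
        pathological chiral network shrinks as concentration rises).
        """
        return replace(
            self,
            gamma_range=(0.0, math.pi / 4.0),
            n_needles=max(2, round(0.6 * self.n_needles)),
            needle_length=(1.3 * self.needle_length[0], 1.3 * self.needle_length[1]),
            n_spherulites=round(2.0 * self.n_spherulites),
            cb_mean=1.5 * self.cb_mean,
            cb_sd=0.5 * self.cb_sd,
        )


@dataclass(frozen=True)
class CohortSpec:
    """Two-group sampling design (healthy-like vs pathology-like)."""

    healthy: PhantomSpec
    pathology: PhantomSpec
    n_per_group: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        h, p = self.healthy.gamma_range, self.pathology.gamma_range
        if not (h[0] <= p[0] and p[1] <= h[1]):
            raise ValueError("pathology orientation range must be within the healthy range")

    @classmethod
    def default(cls, grid: tuple[int, int] = (1120, 960), n_per_group: int = 26, seed: int = 0) -> "CohortSpec":
        healthy = PhantomSpec.default(grid)
        return cls(healthy=healthy, pathology=healthy.pathology_like(), n_per_group=n_per_group, seed=seed)


@dataclass
class Sample:
    """One synthetic facies: composite Jones field plus per-layer truth."""

    sample_id: str
    group: str
    seed: int
    jones: np.ndarray  # (A, B, 2, 2) complex
    truth: list[AnisotropyState]  # per-layer ground truth

    @property
    def truth_total(self) -> AnisotropyState:
        out = self.truth[0]
        for st in self.truth[1:]:
            out = out.add(st)
        return out


def draw_orientations(spec: PhantomSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n needle optical-axis angles under the spec's orientation law."""
    if spec.gamma_kappa is None:
        return rng.uniform(spec.gamma_range[0], spec.gamma_range[1], size=n)
    mu = 0.5 * (spec.gamma_range[0] + spec.gamma_range[1])
    return np.clip(rng.vonmises(mu, spec.gamma_kappa, size=n), *spec.gamma_range)


def _thick_line(canvas: np.ndarray, r0: float, c0: float, r1: float, c1: float, width: float, value: complex) -> None:
    """Accumulate an anti-aliased line of the given width onto a complex canvas."""
    H, W = canvas.shape
    n_off = max(1, int(round(width)))
    # offsets perpendicular to the line axis
    dr, dc = r1 - r0, c1 - c0
    norm = math.hypot(dr, dc)
    if norm < 1e-9:
        return
    pr, pc = -dc / norm, dr / norm
    for k in range(n_off):
        off = (k - (n_off - 1) / 2.0)
        rr, cc, val = line_aa(
            int(round(r0 + off * pr)), int(round(c0 + off * pc)),
            int(round(r1 + off * pr)), int(round(c1 + off * pc)),
        )
        keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        np.add.at(canvas, (rr[keep], cc[keep]), value * val[keep])


def render_layer(spec: PhantomSpec, layer_index: int = 0, seed: int | None = None) -> AnisotropyState:
    """Rasterise one layer of the phantom into six anisotropy planes.

    A needle with optical-axis angle ``gamma`` and retardance ``delta``
    contributes ``delta * cos 2 gamma`` to lb_0_90 and ``delta * sin 2 gamma``
    to lb_45_135 (standard retarder decomposition); its dichroism is the
    fixed fraction of the birefringence along the same axis.  Spherulites
    add cb (and the cd fraction) inside discs.  Overlapping structures sum
    (thin-element approximation).  Deterministic for fixed (seed, layer).
    """
    if layer_index >= spec.n_layers:
        raise ValueError("layer_index out of range")
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng([int(base_seed) & 0x7FFFFFFF, int(layer_index)])
    A, B = spec.grid
    cen_r, cen_c = (A - 1) / 2.0, (B - 1) / 2.0
    R = min(A, B) / 2.0

    zeta = np.zeros((A, B), dtype=complex)  # lb_0_90 + i * lb_45_135
    z0, z1, _ = spec.zones

    # dendritic needles in the transitional + edge annulus
    for _ in range(spec.n_needles):
        rad = R * math.sqrt(rng.uniform(z0 * z0, 1.0))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r_c = cen_r + rad * math.sin(theta)
        c_c = cen_c + rad * math.cos(theta)
        gamma = float(draw_orientations(spec, 1, rng)[0])
        delta = max(0.0, rng.normal(spec.delta_mean, spec.delta_sd))
        length = rng.uniform(*spec.needle_length)
        width = rng.uniform(*spec.needle_width)
        hr = 0.5 * length * math.sin(gamma)
        hc = 0.5 * length * math.cos(gamma)
        _thick_line(zeta, r_c - hr, c_c - hc, r_c + hr, c_c + hc, width, delta * np.exp(2j * gamma))

    # spherulites in the central + transitional disc
    cb = np.zeros((A, B))
    for _ in range(spec.n_spherulites):
        rad = R * math.sqrt(rng.uniform(0.0, z1 * z1))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r_c = cen_r + rad * math.sin(theta)
        c_c = cen_c + rad * math.cos(theta)
        amp = max(0.0, rng.normal(spec.cb_mean, spec.cb_sd))
        rr, cc = draw_disk((r_c, c_c), rng.uniform(*spec.spherulite_radius), shape=(A, B))
        cb[rr, cc] += amp

    if spec.smooth_sigma > 0:
        zeta = ndimage.gaussian_filter(zeta.real, spec.smooth_sigma) + 1j * ndimage.gaussian_filter(
            zeta.imag, spec.smooth_sigma
        )
        cb = ndimage.gaussian_filter(cb, spec.smooth_sigma)

    lb_0_90, lb_45_135 = zeta.real, zeta.imag
    return AnisotropyState(
        lb_0_90=lb_0_90,
        lb_45_135=lb_45_135,
        cb=cb,
        ld_0_90=spec.dichroism_fraction * lb_0_90,
        ld_45_135=spec.dichroism_fraction * lb_45_135,
        cd=spec.cd_fraction * cb,
    )


def render_jones_field(spec: PhantomSpec, seed: int | None = None) -> tuple[np.ndarray, list[AnisotropyState]]:
    """Compose the per-layer phantom into one Jones matrix field.

    Returns the pixelwise product over layers (layer 0 first along the beam)
    together with the per-layer ground-truth states.
    """
    states = [render_layer(spec, k, seed=seed) for k in range(spec.n_layers)]
    fields = [jones_forward(st) for st in states]
    return stack_product(fields), states


def make_cohort(cohort: CohortSpec) -> list[Sample]:
    """Generate both groups with per-sample seeds derived from the cohort seed."""
    ss = np.random.SeedSequence(cohort.seed)
    children = ss.spawn(2 * cohort.n_per_group)
    samples: list[Sample] = []
    for i, (group, spec) in enumerate([("healthy", cohort.healthy), ("pathology", cohort.pathology)]):
        for j in range(cohort.n_per_group):
            child = children[i * cohort.n_per_group + j]
            seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
            W, truth = render_jones_field(spec, seed=seed)
            samples.append(Sample(sample_id=f"{group}_{j:03d}", group=group, seed=seed, jones=W, truth=truth))
    return samples
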