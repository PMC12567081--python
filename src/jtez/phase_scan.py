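"""Layer-by-layer phase scanning of a recovered complex-amplitude field.

Pixels of the reconstructed object field are selected by their accumulated
phase: weakly scattered (optically thin) components carry a small phase, so
gating the field at decreasing phase planes ``phi_k`` (pi/2, pi/4, pi/8)
isolates components of decreasing scattering multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .interferometry import RecoveredField

__all__ = ["PhaseSection", "EmptySectionError", "pixel_phase", "section_mask", "layered_field", "DEFAULT_PLANES"]

#: phase planes scanned by default, largest first
DEFAULT_PLANES = (math.pi / 2.0, math.pi / 4.0, math.pi / 8.0)

#: |w21/w11| below this is treated as no measurable inter-component split
RATIO_FLOOR = 0.02


class EmptySectionError(ValueError):
    """A phase section retained no pixels."""


@dataclass(frozen=True)
class PhaseSection:
    """One phase plane of the scan.

    ``cumulative`` mode keeps accumulated phase <= ``phi_k``; ``band`` mode
    keeps a window of width ``delta_phi`` around ``phi_k``.
    """

    phi_k: float
    delta_phi: float = math.pi / 16.0
    mode: str = "cumulative"

    def __post_init__(self) -> None:
        if not (0.0 < self.phi_k <= 2.0 * math.pi):
            raise ValueError("phi_k must be in (0, 2*pi]")
        if not (0.0 < self.delta_phi <= 2.0 * math.pi):
            raise ValueError("delta_phi must be in (0, 2*pi]")
        if self.mode not in ("cumulative", "band"):
            raise ValueError(f"unknown scan mode {self.mode!r}")


def pixel_phase(rec: RecoveredField, functional: str = "anisotropy", ratio_floor: float = RATIO_FLOOR) -> np.ndarray:
    """Accumulated-phase map in [0, 2*pi).

    ``functional="anisotropy"`` (default): the accumulated anisotropy phase
    read from the trace, ``2 arccos(0.5 Re(w11 + w22))`` — equal to the
    retardance delta for any pure retarder and growing with the number of
    anisotropic interactions a pixel has accumulated, which is what the
    layer-by-layer gate needs.  Apply after piston removal.

    ``functional="retardation"``: the phase split between the orthogonal
    components under 0-degree irradiation, ``|arg(w21 / w11)|`` (piston
    invariant but orientation- rather than magnitude-sensitive for weak
    pixels).  Where the cross component is below ``ratio_floor * |w11|``
    the split is read from the diagonal instead, ``2 |arg w11|`` (the two
    agree for a diagonal unimodular retarder).

    ``functional="total"``: the direct path phase ``|arg w11|``.
    """
    if not np.any(rec.mask):
        raise ValueError("empty validity mask")
    w11 = rec.w[..., 0, 0]
    w21 = rec.w[..., 1, 0]
    if functional == "anisotropy":
        tr = 0.5 * (w11.real + rec.w[..., 1, 1].real)
        phi = 2.0 * np.arccos(np.clip(tr, -1.0, 1.0))
    elif functional == "total":
        phi = np.abs(np.angle(w11))
    elif functional == "retardation":
        safe = np.abs(w21) >= ratio_floor * np.abs(w11)
        ratio = np.where(safe, w21, 1.0) / np.where(w11 == 0, 1.0, w11)
        phi = np.where(safe, np.abs(np.angle(ratio)), 2.0 * np.abs(np.angle(w11)))
    else:
        raise ValueError(f"unknown phase functional {functional!r}")
    return np.mod(phi, 2.0 * np.pi)


def section_mask(
    phase_map: np.ndarray,
    section: PhaseSection,
    base_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Boolean pixel gate for one phase section and its retained count K."""
    if section.mode == "cumulative":
        keep = phase_map <= section.phi_k
    else:
        keep = np.abs(phase_map - section.phi_k) <= section.delta_phi / 2.0
    if base_mask is not None:
        keep = keep & base_mask
    k = int(np.count_nonzero(keep))
    if k == 0:
        raise EmptySectionError(f"no pixels retained at phi_k={section.phi_k:.4g} ({section.mode})")
    return keep, k


def layered_field(rec: RecoveredField, section: PhaseSection, functional: str = "anisotropy") -> RecoveredField:
    """Restrict a recovered field to one phase section (values untouched)."""
    phi = pixel_phase(rec, functional=functional)
    keep, _ = section_mask(phi, section, base_mask=rec.mask)
    out = rec.copy()
    out.mask = keep
    out.phase_plane = float(section.phi_k)
    return out
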