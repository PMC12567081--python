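"""Statistical-moment markers Z1-Z4 of theziograms.

Population central moments of the map values over the valid pixels:
Z1 the mean, Z2 the spread, Z3 the standardized skewness, Z4 the kurtosis.
By default Z2 is the standard deviation (the 1/Z2^3 and 1/Z2^4 skew/kurt
normalisations are dimensionless only then) and Z4 is the *excess*
kurtosis, so a Gaussian map gives Z3 = Z4 = 0; flags restore the literal
variance / raw-kurtosis readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .theziography import Theziogram

__all__ = ["StatMarkers", "DegenerateDistributionError", "central_moments", "marker_table", "MARKER_NAMES"]

MARKER_NAMES = ("Z1", "Z2", "Z3", "Z4")


class DegenerateDistributionError(ValueError):
    """Zero spread: Z3 and Z4 are undefined."""


@dataclass(frozen=True)
class StatMarkers:
    """The four moment markers of one map, with bookkeeping tags."""

    z1: float
    z2: float
    z3: float | None
    z4: float | None
    k: int
    parameter: str = ""
    phase_plane: str | float = "integral"

    @property
    def degenerate(self) -> bool:
        return self.z3 is None

    def as_dict(self) -> dict:
        return {
            "Z1": self.z1,
            "Z2": self.z2,
            "Z3": np.nan if self.z3 is None else self.z3,
            "Z4": np.nan if self.z4 is None else self.z4,
            "K": self.k,
        }


def central_moments(
    data: Theziogram | np.ndarray,
    mask: np.ndarray | None = None,
    z2_is_variance: bool = False,
    raw_kurtosis: bool = False,
    strict: bool = False,
) -> StatMarkers:
    """Population moment markers of a theziogram or plain array.

    ``strict=True`` raises :class:`DegenerateDistributionError` on constant
    maps; otherwise Z3/Z4 are reported as ``None`` (not NaN-propagated).
    """
    parameter, plane = "", "integral"
    if isinstance(data, Theziogram):
        values = data.masked_values()
        parameter, plane = data.parameter, data.phase_plane
    else:
        values = np.asarray(data, float)
        if mask is not None:
            values = values[mask]
        values = values.ravel()
    k = values.size
    if k < 2:
        raise ValueError("need at least 2 pixels")

    z1 = float(values.mean())
    dev = values - z1
    m2 = float(np.mean(dev**2))
    sd = float(np.sqrt(m2))
    z2 = m2 if z2_is_variance else sd
    if sd == 0.0:
        if strict:
            raise DegenerateDistributionError("zero spread; Z3, Z4 undefined")
        z3 = z4 = None
    else:
        z3 = float(np.mean(dev**3) / sd**3)
        z4 = float(np.mean(dev**4) / sd**4)
        if not raw_kurtosis:
            z4 -= 3.0
    return StatMarkers(z1=z1, z2=z2, z3=z3, z4=z4, k=k, parameter=parameter, phase_plane=plane)


def marker_table(
    samples: Iterable[tuple[str, str, dict[tuple[str, str | float], Theziogram]]],
    z2_is_variance: bool = False,
    raw_kurtosis: bool = False,
) -> pd.DataFrame:
    """Long-format marker table over samples x parameters x phase planes.

    ``samples`` yields ``(sample_id, group, maps)`` where ``maps`` is keyed
    by ``(parameter, phase_plane)``.  One row per key, deterministic order.
    """
    rows = []
    for sample_id, group, maps in samples:
        for (parameter, plane), tz in sorted(maps.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
            m = central_moments(tz, z2_is_variance=z2_is_variance, raw_kurtosis=raw_kurtosis)
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "parameter": parameter,
                    "phase_plane": str(plane),
                    **m.as_dict(),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["sample_id", "parameter", "phase_plane"], kind="stable").reset_index(drop=True)
    return df
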