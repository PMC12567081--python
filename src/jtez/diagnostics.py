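"""Diagnostic-power evaluation: confusion counts, Se/Sp/Ac, grading.

Sensitivity is the true-positive fraction of the experimental group,
specificity the true-negative fraction of the control group, and accuracy
the fraction of correct calls over all samples (equal to balanced accuracy
when the groups have the same size).  Percentages are rounded half-up to
one decimal.  A leave-one-out Youden-threshold classifier turns per-sample
marker values into confusion counts; it is a transparent default, not a
claim about any particular instrument's procedure.

``PRINTED_COUNTS`` ships the published worked-example table of confusion
counts for the Jones-matrix (JT) and Mueller-matrix (MMT) readings of the
four anisotropy markers over three group comparisons; ``verify_printed_
counts`` recomputes every percentage from its counts and flags the one
internally inconsistent cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "DiagnosticResult",
    "se_sp_ac",
    "grade",
    "classify_loo",
    "representativeness",
    "verify_printed_counts",
    "PRINTED_COUNTS",
    "GRADES",
]

GRADES = ("unsatisfactory", "satisfactory", "good", "very good", "excellent")


def _round1(x: float) -> float:
    """Round half-up to one decimal (matches the printed percentages)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts: N/n true/false of the experimental group Q,
    H/h true/false of the control group G."""

    n_tp: int
    n_fn: int
    h_tn: int
    h_fp: int

    def __post_init__(self) -> None:
        for v in (self.n_tp, self.n_fn, self.h_tn, self.h_fp):
            if v < 0:
                raise ValueError("confusion counts must be >= 0")
        if self.q_size == 0 or self.g_size == 0:
            raise ValueError("empty group")

    @property
    def q_size(self) -> int:
        return self.n_tp + self.n_fn

    @property
    def g_size(self) -> int:
        return self.h_tn + self.h_fp


@dataclass(frozen=True)
class DiagnosticResult:
    """Se/Sp/Ac percentages (1 decimal), accuracy grade, and balance flag."""

    se: float
    sp: float
    ac: float
    grade: str
    balanced: bool
    marker_id: str = ""
    counts: ConfusionCounts | None = None


def grade(ac: float) -> str:
    """Accuracy grade on half-open bands anchored at 80/85/90/95."""
    if not (0.0 <= ac <= 100.0):
        raise ValueError("accuracy out of [0, 100]")
    if ac <= 80.0:
        return "unsatisfactory"
    if ac <= 85.0:
        return "satisfactory"
    if ac <= 90.0:
        return "good"
    if ac <= 95.0:
        return "very good"
    return "excellent"


def se_sp_ac(counts: ConfusionCounts, marker_id: str = "") -> DiagnosticResult:
    """Sensitivity, specificity and accuracy of one confusion table."""
    se = _round1(100.0 * counts.n_tp / counts.q_size)
    sp = _round1(100.0 * counts.h_tn / counts.g_size)
    ac = _round1(100.0 * (counts.n_tp + counts.h_tn) / (counts.q_size + counts.g_size))
    return DiagnosticResult(
        se=se, sp=sp, ac=ac, grade=grade(ac), balanced=counts.q_size == counts.g_size,
        marker_id=marker_id, counts=counts,
    )


def _best_threshold(control: np.ndarray, experimental: np.ndarray) -> tuple[float, int]:
    """Youden-J-optimal threshold on training values.

    Returns (threshold, polarity) with polarity +1 when the experimental
    group lies above the threshold.  Ties in J resolve to the midpoint
    between the two group means.
    """
    polarity = 1 if experimental.mean() >= control.mean() else -1
    values = np.sort(np.unique(np.concatenate([control, experimental])))
    if values.size == 1:
        return float(values[0]), polarity
    cuts = 0.5 * (values[:-1] + values[1:])
    if polarity > 0:
        j = np.array([np.mean(experimental > c) + np.mean(control <= c) - 1.0 for c in cuts])
    else:
        j = np.array([np.mean(experimental < c) + np.mean(control >= c) - 1.0 for c in cuts])
    best = j >= j.max() - 1e-12
    midpoint = 0.5 * (control.mean() + experimental.mean())
    if j.max() <= 1e-12:  # degenerate separation: chance-level either way
        return float(midpoint), polarity
    # ties resolve toward the midpoint between the two group means
    optimal = cuts[best]
    return float(optimal[np.argmin(np.abs(optimal - midpoint))]), polarity


def classify_loo(
    markers_control: np.ndarray,
    markers_experimental: np.ndarray,
    marker_id: str = "",
) -> ConfusionCounts:
    """Leave-one-out threshold classification of two marker-value groups.

    For every held-out sample the Youden-optimal threshold is fit on the
    remaining samples and the held-out value is classified by side of the
    threshold; counts accumulate over all folds.  Fully deterministic.
    """
    control = np.asarray(markers_control, float)
    experimental = np.asarray(markers_experimental, float)
    if control.size < 2 or experimental.size < 2:
        raise ValueError("need at least 2 samples per group")

    n_tp = n_fn = h_tn = h_fp = 0
    for i in range(experimental.size):
        train_e = np.delete(experimental, i)
        cut, pol = _best_threshold(control, train_e)
        positive = experimental[i] > cut if pol > 0 else experimental[i] < cut
        n_tp += int(positive)
        n_fn += int(not positive)
    for i in range(control.size):
        train_c = np.delete(control, i)
        cut, pol = _best_threshold(train_c, experimental)
        positive = control[i] > cut if pol > 0 else control[i] < cut
        h_fp += int(positive)
        h_tn += int(not positive)
    return ConfusionCounts(n_tp=n_tp, n_fn=n_fn, h_tn=h_tn, h_fp=h_fp)


def representativeness(marker_table: pd.DataFrame, threshold: float = 0.025) -> pd.DataFrame:
    """Leave-one-out stability of each marker's group mean.

    For every (group, parameter, phase_plane, Z-column) the standard
    deviation of the jackknife (leave-one-sample-out) fold means is
    computed; markers above ``threshold`` are flagged as unstable.
    """
    rows = []
    for (group, parameter, plane), sub in marker_table.groupby(["group", "parameter", "phase_plane"]):
        for z in ("Z1", "Z2", "Z3", "Z4"):
            vals = sub[z].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            n = vals.size
            if n < 2:
                continue
            total = vals.sum()
            fold_means = (total - vals) / (n - 1)
            sd = float(fold_means.std(ddof=0))
            rows.append(
                {
                    "group": group,
                    "parameter": parameter,
                    "phase_plane": plane,
                    "marker": z,
                    "fold_sd": sd,
                    "pass": sd <= threshold,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# published worked-example confusion counts (three comparisons: control "1"
# vs early "2", control "1" vs advanced "3", early "2" vs advanced "3";
# Q = G = 26 per group).  Each row: method, parameter, comparison, counts
# and the printed percentages.
_ROW = ("method", "parameter", "comparison", "N", "n", "H", "h", "printed_se", "printed_sp", "printed_ac")
PRINTED_COUNTS: tuple[dict, ...] = tuple(
    dict(zip(_ROW, r))
    for r in [
        ("JT", "LB", "1v2", 23, 3, 23, 3, 88.5, 88.5, 88.5),
        ("JT", "LB", "1v3", 25, 1, 24, 2, 96.2, 88.5, 94.2),  # printed Sp inconsistent with its counts
        ("JT", "LB", "2v3", 24, 2, 24, 2, 92.3, 92.3, 92.3),
        ("MMT", "LB", "1v2", 20, 6, 20, 6, 76.9, 76.9, 76.9),
        ("MMT", "LB", "1v3", 23, 3, 22, 4, 88.5, 84.6, 86.5),
        ("MMT", "LB", "2v3", 21, 5, 22, 4, 80.8, 84.6, 82.7),
        ("JT", "CB", "1v2", 24, 2, 23, 3, 92.3, 88.5, 90.4),
        ("JT", "CB", "1v3", 25, 1, 25, 1, 96.2, 96.2, 96.2),
        ("JT", "CB", "2v3", 25, 1, 24, 2, 96.2, 92.3, 94.2),
        ("MMT", "CB", "1v2", 21, 5, 20, 6, 80.8, 76.9, 78.8),
        ("MMT", "CB", "1v3", 24, 2, 22, 4, 92.3, 84.6, 88.5),
        ("MMT", "CB", "2v3", 23, 3, 21, 5, 88.5, 80.8, 84.6),
        ("JT", "LD", "1v2", 22, 4, 21, 5, 84.6, 80.8, 82.7),
        ("JT", "LD", "1v3", 25, 1, 23, 3, 96.2, 88.5, 92.3),
        ("JT", "LD", "2v3", 23, 3, 24, 2, 88.5, 92.3, 90.4),
        ("MMT", "LD", "1v2", 18, 8, 19, 7, 69.2, 73.1, 71.2),
        ("MMT", "LD", "1v3", 20, 6, 20, 6, 76.9, 76.9, 76.9),
        ("MMT", "LD", "2v3", 17, 9, 16, 10, 65.4, 61.5, 63.5),
        ("JT", "CD", "1v2", 23, 3, 23, 3, 88.5, 88.5, 88.5),
        ("JT", "CD", "1v3", 24, 2, 25, 1, 92.3, 96.2, 94.2),
        ("JT", "CD", "2v3", 24, 2, 24, 2, 92.3, 92.3, 92.3),
        ("MMT", "CD", "1v2", 19, 7, 18, 8, 73.1, 69.2, 71.2),
        ("MMT", "CD", "1v3", 20, 6, 19, 7, 76.9, 73.1, 75.0),
        ("MMT", "CD", "2v3", 19, 7, 18, 8, 73.1, 69.2, 71.2),
    ]
)


def verify_printed_counts(rows: tuple[dict, ...] = PRINTED_COUNTS) -> pd.DataFrame:
    """Recompute Se/Sp/Ac/grade from each row's confusion counts.

    Returns a table with the recomputed values, the printed ones, and
    agreement flags (at the printed 0.1% precision).  One shipped row is
    known to disagree on Sp (its printed cell repeats the neighbouring
    comparison's value); it is reported, not silently fixed.
    """
    out = []
    for row in rows:
        counts = ConfusionCounts(n_tp=row["N"], n_fn=row["n"], h_tn=row["H"], h_fp=row["h"])
        res = se_sp_ac(counts, marker_id=f"{row['method']}:{row['parameter']}:{row['comparison']}")
        out.append(
            {
                **{k: row[k] for k in ("method", "parameter", "comparison", "N", "n", "H", "h")},
                "se": res.se,
                "sp": res.sp,
                "ac": res.ac,
                "grade": res.grade,
                "printed_se": row["printed_se"],
                "printed_sp": row["printed_sp"],
                "printed_ac": row["printed_ac"],
                "se_agrees": abs(res.se - row["printed_se"]) < 0.05,
                "sp_agrees": abs(res.sp - row["printed_sp"]) < 0.05,
                "ac_agrees": abs(res.ac - row["printed_ac"]) < 0.05,
            }
        )
    return pd.DataFrame(out)
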