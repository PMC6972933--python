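"""Hemispheric laterality: LI = (L - R) / (L + R), group summaries, t-test.

The laterality index maps a left/right pair of non-negative measurements
(tract count, volume, mean FA) onto [-1, +1]: +1 is completely
left-lateralized, -1 completely right-lateralized, 0 symmetric.  When
both sides are zero the index is undefined and propagates as NaN; group
summaries exclude undefined values and report how many were dropped.

Left and right values come from the same subjects, so the default
significance test is the two-sided *paired* Student t-test on the
left-vs-right subject values; an unpaired variant is available by flag.
A zero-variance difference with nonzero mean is flagged degenerate
(infinite statistic) rather than silently reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["laterality_index", "GroupSummary", "summarize_subjects"]


def laterality_index(L: float, R: float) -> float:
    """(L - R) / (L + R); NaN (undefined) when L + R == 0.

    Raises on negative inputs — the index is defined for magnitudes.
    """
    if L < 0 or R < 0:
        raise ValueError(f"laterality index needs non-negative inputs, got L={L}, R={R}")
    total = L + R
    if total == 0:
        return math.nan
    return (L - R) / total


@dataclass(frozen=True)
class GroupSummary:
    """Across-subject summary of one lateralized quantity."""

    quantity: str
    n_subjects: int
    mean_left: float
    sem_left: float
    mean_right: float
    sem_right: float
    mean_li: float
    sem_li: float
    n_undefined: int          # subjects with L + R == 0, excluded from LI stats
    t_statistic: float
    p_value: float
    significant: bool         # p < 0.05
    paired: bool
    degenerate: bool          # zero-variance paired differences with nonzero mean


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return math.nan
    return float(values.std(ddof=1) / math.sqrt(len(values)))


def summarize_subjects(
    left: np.ndarray, right: np.ndarray, quantity: str = "n_tracts", paired: bool = True
) -> GroupSummary:
    """Mean +/- SEM of left, right and LI over subjects, plus the t-test
    on left vs right values."""
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("left and right must be 1-D arrays over the same subjects")
    n = len(left)
    if n < 2:
        raise ValueError("need at least 2 subjects for SEM and t-test")
    if (left < 0).any() or (right < 0).any():
        raise ValueError("laterality inputs must be non-negative")

    li = np.array([laterality_index(l, r) for l, r in zip(left, right)])
    defined = ~np.isnan(li)
    n_undefined = int((~defined).sum())
    li_def = li[defined]

    degenerate = False
    if paired:
        diff = left - right
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                t_stat, p = 0.0, 1.0
            else:
                t_stat = math.inf if diff.mean() > 0 else -math.inf
                p = 0.0
                degenerate = True
        else:
            t_stat, p = stats.ttest_rel(left, right)
    else:
        t_stat, p = stats.ttest_ind(left, right)
        if not np.isfinite(t_stat):
            degenerate = True

    return GroupSummary(
        quantity=quantity,
        n_subjects=n,
        mean_left=float(left.mean()),
        sem_left=_sem(left),
        mean_right=float(right.mean()),
        sem_right=_sem(right),
        mean_li=float(li_def.mean()) if len(li_def) else math.nan,
        sem_li=_sem(li_def),
        n_undefined=n_undefined,
        t_statistic=float(t_stat),
        p_value=float(p),
        significant=bool(p < 0.05),
        paired=paired,
        degenerate=degenerate,
    )
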