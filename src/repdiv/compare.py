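"""Two-group comparison statistics for per-animal diversity measures.

Groups (e.g. wild-type vs transgenic animals) are compared one measure at a
time with an unpaired two-sided test: Student's t by default (Welch by
flag) or Mann-Whitney.  Fold change is mean(B)/mean(A); dispersion is
reported as SEM = SD/sqrt(n) with SD the n-1 sample standard deviation.
No multiple-testing correction is applied by default — the comparisons are
reported raw, each with significance stars at 0.05/0.01/0.001 — but a
Benjamini-Hochberg adjustment over a batch of comparisons is available as
an explicit opt-in.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats as sps

TESTS = ("unpaired_t", "mann_whitney")


@dataclasses.dataclass
class GroupComparison:
    measure: str
    values_a: List[float]
    values_b: List[float]
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    fold_change: float
    test: str
    statistic: Optional[float]
    pvalue: Optional[float]
    stars: str
    degenerate: bool = False
    pvalue_adjusted: Optional[float] = None


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return math.nan
    return float(values.std(ddof=1) / math.sqrt(values.size))


def significance_stars(p: Optional[float]) -> str:
    if p is None or math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "unpaired_t",
    measure: str = "measure",
    equal_var: bool = True,
) -> GroupComparison:
    """Compare one measure between two groups of animals.

    ``unpaired_t`` runs Student's two-sample t-test (``equal_var=False``
    switches to Welch); ``mann_whitney`` runs the two-sided Mann-Whitney U.
    With fewer than 2 values in a group, or two identical constant groups
    (zero variance everywhere), the comparison is descriptive only and
    flagged degenerate with p = 1.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold = mean_b / mean_a if mean_a != 0 else math.nan

    degenerate = (
        a.size < 2
        or b.size < 2
        or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0])
    )
    if degenerate:
        stat, p = None, 1.0
    elif test == "unpaired_t":
        stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
        stat, p = float(stat), float(p)
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(stat), float(p)

    return GroupComparison(
        measure=measure,
        values_a=[float(x) for x in a],
        values_b=[float(x) for x in b],
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=_sem(a),
        sem_b=_sem(b),
        fold_change=fold,
        test=test + ("" if test != "unpaired_t" else ("_student" if equal_var else "_welch")),
        statistic=stat,
        pvalue=p,
        stars=significance_stars(p),
        degenerate=degenerate,
    )


def adjust_benjamini_hochberg(comparisons: Sequence[GroupComparison]) -> None:
    """Optional BH adjustment across a batch of comparisons (in place).

    Off by default in every pipeline path; raw p-values remain untouched in
    ``pvalue``, the adjusted values go to ``pvalue_adjusted``.
    """
    ps = np.array([c.pvalue if c.pvalue is not None else 1.0 for c in comparisons])
    order = np.argsort(ps)
    m = len(ps)
    adjusted = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        idx = order[rank_idx]
        running = min(running, ps[idx] * m / (rank_idx + 1))
        adjusted[idx] = running
    for c, q in zip(comparisons, adjusted):
        c.pvalue_adjusted = float(q)
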