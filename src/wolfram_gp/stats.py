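"""Group summaries and pairwise Wilcoxon rank-sum comparisons.

Age-of-onset distributions are summarized per dose group with box-plot
statistics (median, quartiles, 1.5×IQR whiskers, outliers) and compared
pairwise with two-sided Wilcoxon rank-sum tests; within each comparison
family the pairwise p-values receive a Bonferroni adjustment
(p_adj = min(1, m·p) with m the number of pairwise tests in that family —
one manifestation × one grouping, never across manifestations).

The exact test enumerates the null distribution of the rank sum by dynamic
programming (feasible for small samples, untied data); the large-sample
path uses mid-ranks with the usual tie-corrected normal approximation and
no continuity correction by default.
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import norm, rankdata

from .cohort import GroupedPatient, Manifestation, Sex

logger = logging.getLogger(__name__)

__all__ = [
    "Grouping",
    "FiveNumberSummary",
    "PairwiseTest",
    "GroupComparison",
    "five_number_summary",
    "wilcoxon_rank_sum",
    "bonferroni_adjust",
    "compare_dose_groups",
    "sex_stratified_comparison",
]

QUARTILE_METHODS = ("linear", "lower", "midpoint")

#: auto mode uses exact enumeration up to this combined sample size
EXACT_MAX_TOTAL_N = 20


class Grouping(Enum):
    NSFS_DOSE = "nsfs_dose"
    TM_DOSE_TWO_INFRAME = "tm_dose_two_inframe"
    TM_DOSE_ONE_INFRAME = "tm_dose_one_inframe"
    SEX = "sex"


@dataclass(frozen=True)
class FiveNumberSummary:
    """Box-plot statistics for one group's onset ages (years).

    Whiskers extend to the most extreme observations within 1.5×IQR of the
    box edges; observations beyond the whiskers are outliers.
    """

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    u_statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparison:
    """Per-group summaries plus pairwise rank-sum tests for one grouping."""

    manifestation: Manifestation
    grouping: Grouping
    per_group: dict[str, FiveNumberSummary]
    pairwise: tuple[PairwiseTest, ...]
    notes: tuple[str, ...] = field(default=())

    @property
    def testable(self) -> bool:
        return len(self.pairwise) > 0


def five_number_summary(ages, method: str = "linear") -> FiveNumberSummary:
    """Median, quartiles, 1.5×IQR whiskers and outliers for a sample of ages.

    ``method`` selects the quartile interpolation convention among
    ``linear`` (interpolate between order statistics; the common default),
    ``lower`` and ``midpoint``.
    """
    x = np.asarray(list(ages), dtype=float)
    if x.size == 0:
        raise ValueError("five_number_summary requires at least one observation")
    if method not in QUARTILE_METHODS:
        raise ValueError(f"quartile method must be one of {QUARTILE_METHODS}")
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0], method=method)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    # whiskers clamp to actual observations; with every point outside one
    # fence (impossible for both) the box edge is the degenerate whisker
    whisker_low = float(inside.min()) if inside.size else float(q1)
    whisker_high = float(inside.max()) if inside.size else float(q3)
    outliers = tuple(float(v) for v in np.sort(x[(x < whisker_low) | (x > whisker_high)]))
    return FiveNumberSummary(
        n=int(x.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )


@functools.lru_cache(maxsize=256)
def _rank_sum_counts(n_small: int, n_total: int) -> np.ndarray:
    """Number of ways to choose ``n_small`` of ranks 1..n_total with each rank sum.

    Returns counts indexed by rank sum (0..max); standard subset-sum DP.
    The cached array is read-only for callers.
    """
    max_sum = n_small * (2 * n_total - n_small + 1) // 2
    counts = np.zeros((n_small + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        upper = min(rank, n_small)
        for k in range(upper, 0, -1):
            counts[k, rank:] += counts[k - 1, : max_sum + 1 - rank]
    return counts[n_small]


def _exact_two_sided_p(w: float, n_x: int, n_total: int) -> float:
    counts = _rank_sum_counts(n_x, n_total)
    total = counts.sum()
    w_int = int(round(w))
    cdf = counts[: w_int + 1].sum() / total
    sf = counts[w_int:].sum() / total
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_rank_sum(
    x, y, mode: str = "auto", continuity: bool = False
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns ``(U, p)`` where U is the Mann–Whitney statistic for the first
    sample.  ``exact`` enumerates the permutation distribution of the rank
    sum (untied data; the doubled smaller tail is the two-sided p);
    ``normal_approx`` uses mid-ranks with tie-corrected variance; ``auto``
    picks exact when the data are untied and the combined n is at most
    ~20, otherwise the approximation.  A fully tied pooled sample yields
    p = 1 with a degeneracy warning.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires two non-empty samples")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")

    pooled = np.concatenate([x, y])
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    ranks = rankdata(pooled)  # mid-ranks
    w = float(ranks[:n_x].sum())
    u = w - n_x * (n_x + 1) / 2.0

    has_ties = np.unique(pooled).size < n
    if mode == "exact" or (mode == "auto" and not has_ties and n <= EXACT_MAX_TOTAL_N):
        if has_ties:
            logger.info(
                "tied data: exact rank-sum enumeration assumes distinct values; "
                "falling back to the tie-corrected normal approximation"
            )
        else:
            return u, _exact_two_sided_p(w, n_x, n)

    # normal approximation on U with tie-corrected variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        logger.warning("degenerate comparison: all %d pooled values tied", n)
        return u, 1.0
    delta = u - n_x * n_y / 2.0
    if continuity:
        delta -= 0.5 * np.sign(delta)
    z = delta / math.sqrt(var_u)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return u, max(p, np.finfo(float).tiny)


def bonferroni_adjust(p_values) -> list[float]:
    """Bonferroni adjustment: multiply each p by the family size, cap at 1."""
    p_values = list(p_values)
    m = len(p_values)
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    return [min(1.0, p * m) for p in p_values]


def _group_label_fn(grouping: Grouping):
    if grouping is Grouping.NSFS_DOSE:
        return ["NSFS0", "NSFS1", "NSFS2"], lambda p: f"NSFS{p.nsfs_dose}"

    def tm_label(p: GroupedPatient) -> str | None:
        return None if p.tm_dose is None else f"NTM{p.tm_dose}"

    if grouping is Grouping.TM_DOSE_TWO_INFRAME:
        return ["NTM0", "NTM1", "NTM2"], lambda p: tm_label(p) if p.nsfs_dose == 0 else None
    if grouping is Grouping.TM_DOSE_ONE_INFRAME:
        return ["NTM0", "NTM1"], lambda p: tm_label(p) if p.nsfs_dose == 1 else None
    if grouping is Grouping.SEX:
        return (
            ["male", "female"],
            lambda p: p.record.sex.value if p.record.sex is not Sex.UNKNOWN else None,
        )
    raise ValueError(grouping)  # pragma: no cover


def compare_dose_groups(
    patients: list[GroupedPatient],
    manifestation: Manifestation,
    grouping: Grouping,
    quartile_method: str = "linear",
    mode: str = "auto",
) -> GroupComparison:
    """Summarize and pairwise-test onset ages across dose (or sex) groups.

    ``patients`` must be pre-filtered for ``manifestation`` (their
    ``onset_age`` is the tested value).  Patients outside the grouping's
    universe (e.g. one-in-frame patients under the two-in-frame TM
    grouping) are ignored.  Empty groups are omitted and noted; with fewer
    than two non-empty groups the comparison is reported as not testable
    rather than raising.  Bonferroni m = number of pairwise tests here.
    """
    order, label_of = _group_label_fn(grouping)
    values: dict[str, list[float]] = {label: [] for label in order}
    for p in patients:
        label = label_of(p)
        if label is not None:
            values[label].append(p.onset_age)

    notes: list[str] = []
    per_group: dict[str, FiveNumberSummary] = {}
    for label in order:
        if values[label]:
            per_group[label] = five_number_summary(values[label], method=quartile_method)
        else:
            notes.append(f"group {label} empty; omitted")

    nonempty = [label for label in order if label in per_group]
    if len(nonempty) < 2:
        notes.append("not testable: fewer than two non-empty groups")
        return GroupComparison(manifestation, grouping, per_group, (), tuple(notes))

    pairs = list(itertools.combinations(nonempty, 2))
    raw: list[tuple[str, str, float, float]] = []
    for a, b in pairs:
        u, p_val = wilcoxon_rank_sum(values[a], values[b], mode=mode)
        raw.append((a, b, u, p_val))
    adjusted = bonferroni_adjust([r[3] for r in raw])
    pairwise = tuple(
        PairwiseTest(a, b, u, p_val, p_adj)
        for (a, b, u, p_val), p_adj in zip(raw, adjusted)
    )
    return GroupComparison(manifestation, grouping, per_group, pairwise, tuple(notes))


def sex_stratified_comparison(
    patients: list[GroupedPatient],
    manifestation: Manifestation,
    within_dose: int | None = None,
    quartile_method: str = "linear",
    mode: str = "auto",
) -> GroupComparison:
    """Male-vs-female onset comparison, optionally within one NSFS-dose stratum.

    Patients of unknown sex are dropped from this comparison only.
    """
    if within_dose is not None:
        patients = [p for p in patients if p.nsfs_dose == within_dose]
    return compare_dose_groups(
        patients, manifestation, Grouping.SEX, quartile_method=quartile_method, mode=mode
    )
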