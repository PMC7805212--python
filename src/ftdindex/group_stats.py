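"""Matched three-group nonparametric testing and dominant-set identification.

The three study groups are matched in triplets (one NC, one AD, one FTD
subject per triplet), so each measure is compared with the Friedman rank test
over triplets, gatekeeping Wilcoxon signed-rank post hoc tests with Bonferroni
correction over the three pairwise group comparisons.  Measures whose
corrected AD-vs-FTD p falls below alpha are split, by which disease group has
the larger median, into the "FTD dominant" and "AD dominant" sets that the
FTDI model is built on.

The Friedman p-value is exact: under the null every within-triplet ordering is
equally likely, and because a triplet's tie pattern is invariant under
permutation the null distribution of the rank-sum statistic is computed
exactly by dynamic programming over triplets (no chi-square approximation).
An asymptotic option delegates to scipy.  The signed-rank test uses the exact
tie-aware distribution (subset-sum DP over signed ranks) up to 25 non-zero
pairs and the normal approximation with tie and continuity correction beyond.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import MatchingError, NoSignalError, SchemaError
from .volumetry import GROUPS, MeasureMatrix

logger = logging.getLogger(__name__)

PAIRS = (("NC", "AD"), ("NC", "FTD"), ("AD", "FTD"))

#: Largest number of non-zero pairs for which the exact signed-rank
#: distribution is used.
EXACT_WILCOXON_LIMIT = 25


@dataclass
class ComparisonResult:
    """Per-measure outcome of the matched three-group comparison."""

    measure_name: str
    friedman_p: float
    pairwise_p: dict = field(default_factory=dict)  # "NC-AD" etc. -> corrected p
    direction_ad_ftd: str = "none"  # ftd_higher | ad_higher | none


@dataclass
class DominantSets:
    """Measures statistically larger in FTD vs larger in AD, in panel order."""

    ftd_dominant: list
    ad_dominant: list
    alpha: float = 0.05

    def __post_init__(self):
        overlap = set(self.ftd_dominant) & set(self.ad_dominant)
        if overlap:
            raise SchemaError(f"dominant sets overlap: {sorted(overlap)}")

    @property
    def all_measures(self) -> list:
        return list(self.ftd_dominant) + list(self.ad_dominant)

    def to_dict(self) -> dict:
        return {
            "ftd_dominant": list(self.ftd_dominant),
            "ad_dominant": list(self.ad_dominant),
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DominantSets":
        return cls(
            ftd_dominant=list(d["ftd_dominant"]),
            ad_dominant=list(d["ad_dominant"]),
            alpha=float(d.get("alpha", 0.05)),
        )


# ---------------------------------------------------------------------------
# Triplet bookkeeping
# ---------------------------------------------------------------------------

def triplet_blocks(matrix: MeasureMatrix, measure: str) -> np.ndarray:
    """Return an (n_triplets, 3) array of the measure, columns ordered NC, AD, FTD.

    Raises :class:`MatchingError` listing triplet ids that do not contain
    exactly one subject of each group.
    """
    if matrix.triplet_ids is None:
        raise MatchingError("matrix has no triplet ids; matched tests need them")
    col = matrix.column(measure)
    by_triplet: dict[str, dict[str, float]] = {}
    for value, group, tid in zip(col, matrix.groups, matrix.triplet_ids):
        entry = by_triplet.setdefault(tid, {})
        if group in entry:
            raise MatchingError(
                f"triplet {tid!r} has more than one {group} subject", [tid]
            )
        entry[group] = value
    bad = sorted(t for t, e in by_triplet.items() if set(e) != set(GROUPS))
    if bad:
        raise MatchingError(f"incomplete triplets: {bad}", bad)
    if len(by_triplet) < 2:
        raise MatchingError("at least 2 complete triplets are required")
    tids = sorted(by_triplet)
    return np.array([[by_triplet[t][g] for g in GROUPS] for t in tids], dtype=float)


def paired_values(
    matrix: MeasureMatrix, measure: str, pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    blocks = triplet_blocks(matrix, measure)
    ia, ib = GROUPS.index(pair[0]), GROUPS.index(pair[1])
    return blocks[:, ia], blocks[:, ib]


# ---------------------------------------------------------------------------
# Friedman test (exact conditional distribution)
# ---------------------------------------------------------------------------

def _block_ranks2(blocks: np.ndarray) -> np.ndarray:
    """Doubled within-block average ranks (doubling keeps tied ranks integer)."""
    return np.vstack([2 * stats.rankdata(row) for row in blocks]).astype(int)


def _friedman_statistic2(ranks2: np.ndarray) -> float:
    """Sum of squared deviations of doubled-rank column sums from their mean."""
    n = ranks2.shape[0]
    colsums = ranks2.sum(axis=0)
    return float(((colsums - 4 * n) ** 2).sum())


def _friedman_exact_p(blocks: np.ndarray) -> float:
    """Exact permutation p-value of the Friedman statistic for k = 3 groups.

    Each block's rank triple is permuted uniformly over its 3! assignments;
    the joint distribution of the first two column sums is accumulated by
    dynamic programming, which is exact for any number of blocks.
    """
    ranks2 = _block_ranks2(blocks)
    n = ranks2.shape[0]
    s_obs = _friedman_statistic2(ranks2)
    size = 6 * n + 1
    dist = np.zeros((size, size))
    dist[0, 0] = 1.0
    for row in ranks2:
        new = np.zeros_like(dist)
        for a, b, _ in itertools.permutations(row):
            new[a:, b:] += dist[: size - a, : size - b]
        dist = new / 6.0
    r1 = np.arange(size)[:, None]
    r2 = np.arange(size)[None, :]
    r3 = 12 * n - r1 - r2
    s_grid = (r1 - 4 * n) ** 2 + (r2 - 4 * n) ** 2 + (r3 - 4 * n) ** 2
    p = float(dist[s_grid >= s_obs - 1e-9].sum())
    return min(p, 1.0)


def friedman_test(matrix: MeasureMatrix, measure: str, method: str = "exact") -> float:
    """Friedman rank test p-value for one measure across the matched groups.

    ``method="exact"`` (default) computes the exact conditional permutation
    p-value; ``method="asymptotic"`` uses the tie-corrected chi-square
    approximation from scipy.
    """
    blocks = triplet_blocks(matrix, measure)
    if method == "exact":
        return _friedman_exact_p(blocks)
    if method == "asymptotic":
        if np.all(blocks == blocks[:, [0]]):
            return 1.0  # scipy rejects the all-tied degenerate case
        return float(stats.friedmanchisquare(*blocks.T).pvalue)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank post hoc
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p with average ranks for tied magnitudes."""
    ranks2 = (2 * stats.rankdata(np.abs(diffs))).astype(int)
    total = int(ranks2.sum())
    w2 = int(ranks2[diffs > 0].sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        new = pmf.copy()
        new[r:] += pmf[: total + 1 - r]
        pmf = new / 2.0
    p_le = float(pmf[: w2 + 1].sum())
    p_ge = float(pmf[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_posthoc(
    matrix: MeasureMatrix,
    measure: str,
    pair: tuple[str, str] = ("AD", "FTD"),
    paired: bool = True,
) -> float:
    """Two-sided signed-rank p for one group pair (uncorrected).

    Zero differences are dropped (Wilcoxon convention).  Exact distribution up
    to :data:`EXACT_WILCOXON_LIMIT` non-zero pairs, tie/continuity-corrected
    normal approximation beyond.  With ``paired=False`` falls back to the
    Mann-Whitney U test for unmatched cohorts.
    """
    if not paired:
        a = matrix.group_values(measure, pair[0])
        b = matrix.group_values(measure, pair[1])
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    a, b = paired_values(matrix, measure, pair)
    diffs = a - b
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        warnings.warn(
            f"{measure}: all paired differences are zero; p = 1", stacklevel=2
        )
        return 1.0
    if diffs.size <= EXACT_WILCOXON_LIMIT:
        return _signed_rank_exact_p(diffs)
    res = stats.wilcoxon(
        diffs, zero_method="wilcox", correction=True, method="approx",
        alternative="two-sided",
    )
    return float(res.pvalue)


def bonferroni_correct(p: float, k: int = 3) -> float:
    """Bonferroni-corrected p-value, min(1, k*p)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return min(1.0, k * p)


# ---------------------------------------------------------------------------
# Dominant-set identification
# ---------------------------------------------------------------------------

def compare_measure(
    matrix: MeasureMatrix,
    measure: str,
    alpha: float = 0.05,
    paired: bool = True,
    friedman_method: str = "exact",
) -> ComparisonResult:
    """Gatekept comparison of one measure: omnibus test, then post hoc pairs."""
    if paired:
        omnibus_p = friedman_test(matrix, measure, method=friedman_method)
    else:
        groups_present = [g for g in GROUPS if (matrix.groups == g).any()]
        samples = [matrix.group_values(measure, g) for g in groups_present]
        omnibus_p = float(stats.kruskal(*samples).pvalue)
    result = ComparisonResult(measure_name=measure, friedman_p=omnibus_p)
    if omnibus_p >= alpha:
        return result
    groups_present = set(np.unique(matrix.groups))
    for pair in PAIRS:
        if not set(pair) <= groups_present:
            continue
        raw = wilcoxon_posthoc(matrix, measure, pair, paired=paired)
        result.pairwise_p[f"{pair[0]}-{pair[1]}"] = bonferroni_correct(raw, len(PAIRS))
    p_ad_ftd = result.pairwise_p.get("AD-FTD")
    if p_ad_ftd is not None and p_ad_ftd < alpha:
        med_ftd = float(np.median(matrix.group_values(measure, "FTD")))
        med_ad = float(np.median(matrix.group_values(measure, "AD")))
        if med_ftd > med_ad:
            result.direction_ad_ftd = "ftd_higher"
        elif med_ad > med_ftd:
            result.direction_ad_ftd = "ad_higher"
    return result


def compare_all(
    matrix: MeasureMatrix,
    alpha: float = 0.05,
    paired: bool | None = None,
    friedman_method: str = "exact",
) -> list[ComparisonResult]:
    if paired is None:
        paired = matrix.triplet_ids is not None
    return [
        compare_measure(matrix, m, alpha=alpha, paired=paired, friedman_method=friedman_method)
        for m in matrix.measure_names
    ]


def identify_dominant_sets(
    matrix: MeasureMatrix,
    alpha: float = 0.05,
    paired: bool | None = None,
    friedman_method: str = "exact",
) -> DominantSets:
    """Split significantly AD-vs-FTD-different measures by disease direction.

    For each measure the omnibus test gates the Bonferroni-corrected AD-vs-FTD
    post hoc comparison; significant measures join ``ftd_dominant`` when the
    FTD median exceeds the AD median and ``ad_dominant`` otherwise, preserving
    the matrix column order.  Raises :class:`NoSignalError` when both sets end
    up empty.
    """
    results = compare_all(matrix, alpha=alpha, paired=paired, friedman_method=friedman_method)
    ftd_dom = [r.measure_name for r in results if r.direction_ad_ftd == "ftd_higher"]
    ad_dom = [r.measure_name for r in results if r.direction_ad_ftd == "ad_higher"]
    if not ftd_dom and not ad_dom:
        raise NoSignalError(
            "no measure differs between AD and FTD at the chosen alpha; "
            "the FTDI model cannot be fitted"
        )
    sets = DominantSets(ftd_dominant=ftd_dom, ad_dominant=ad_dom, alpha=alpha)
    logger.info("FTD dominant: %s", ftd_dom)
    logger.info("AD dominant: %s", ad_dom)
    return sets


def comparisons_to_dataframe(results: list[ComparisonResult]):
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "measure": r.measure_name,
                "friedman_p": r.friedman_p,
                "p_NC_AD": r.pairwise_p.get("NC-AD"),
                "p_NC_FTD": r.pairwise_p.get("NC-FTD"),
                "p_AD_FTD": r.pairwise_p.get("AD-FTD"),
                "direction_ad_ftd": r.direction_ad_ftd,
            }
        )
    return pd.DataFrame(rows)
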