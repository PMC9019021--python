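"""Site selection and classification statistics.

Top-N by cleavage, factor/cleavage enrichment-ratio classes (the
"BLM-high / BLM-low" construction), occupancy quantile groups, the unpaired
two-sided Wilcoxon rank-sum test, and the 1.5 x IQR boxplot conventions.

Ranking everywhere is descending on the score with ties broken by genomic
order (contig, position) — classifications are therefore equivariant under
permutations of the input list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dsb_signal import DSBSite, genomic_key, window_sum
from .signal_io import SignalTrack


@dataclass
class SiteClassification:
    """Labels per site plus the parameters that produced them."""

    labels: dict[tuple[str, int], object]  # site key -> 'high'/'low'/'unlabeled' or group index
    scores: dict[tuple[str, int], float]
    params: dict = field(default_factory=dict)
    degenerate: bool = False

    def sites_with_label(self, label) -> list[tuple[str, int]]:
        return [k for k, v in self.labels.items() if v == label]


@dataclass
class BoxplotStats:
    """Median/quartile summary with whiskers at the last values inside the
    1.5 x IQR fences and everything beyond flagged as outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class GroupComparison:
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    method: str  # 'exact' or 'normal_approx'
    n_a: int
    n_b: int
    summary_a: BoxplotStats
    summary_b: BoxplotStats


def _sorted_desc(sites: list[DSBSite], score_of) -> list[DSBSite]:
    return sorted(sites, key=lambda s: (-score_of(s), genomic_key(s)))


def top_n_by_cleavage(sites: list[DSBSite], n: int = 80) -> list[DSBSite]:
    """The n best-cleaved sites (highest cleavage_score; ties genomic)."""
    if n > len(sites):
        raise ValueError(f"requested {n} sites but only {len(sites)} available")
    return _sorted_desc(sites, lambda s: s.cleavage_score)[:n]


def ratio_classify(
    sites: list[DSBSite],
    factor_track: SignalTrack,
    cleavage_track: SignalTrack,
    signal_window: int = 4_000,
    cleavage_window: int = 1_000,
    n_extreme: int = 20,
    pseudocount: float = 1.0,
) -> SiteClassification:
    """Classify sites by the factor/cleavage enrichment ratio.

    Per site, score = (factor signal in signal_window + pseudocount) /
    (cleavage signal in cleavage_window + pseudocount); sites are ranked by
    this ratio and the top n_extreme labeled 'high', bottom n_extreme 'low',
    rest 'unlabeled'.  The ratio normalizes recruitment by how well the site
    was actually cut, separating genuine enrichment from cleavage efficiency.
    """
    if 2 * n_extreme > len(sites):
        raise ValueError("2 * n_extreme exceeds the number of sites")
    scores = {}
    for s in sites:
        num = window_sum(factor_track, s, signal_window) + pseudocount
        den = window_sum(cleavage_track, s, cleavage_window) + pseudocount
        if den == 0:
            raise ValueError(
                f"zero cleavage signal at {genomic_key(s)} with zero pseudocount; "
                "set pseudocount > 0"
            )
        scores[genomic_key(s)] = num / den
    ranked = _sorted_desc(sites, lambda s: scores[genomic_key(s)])
    labels: dict[tuple[str, int], object] = {
        genomic_key(s): "unlabeled" for s in sites
    }
    for s in ranked[:n_extreme]:
        labels[genomic_key(s)] = "high"
    for s in ranked[-n_extreme:]:
        labels[genomic_key(s)] = "low"
    vals = list(scores.values())
    return SiteClassification(
        labels=labels,
        scores=scores,
        params=dict(
            signal_window=signal_window,
            cleavage_window=cleavage_window,
            n_extreme=n_extreme,
            pseudocount=pseudocount,
        ),
        degenerate=(max(vals) == min(vals)),
    )


def quantile_groups(
    sites: list[DSBSite],
    score_field: str = "transcription_score",
    n_groups: int = 4,
) -> SiteClassification:
    """Split sites into contiguous rank groups on a score (group 0 highest).

    With N divisible by n_groups all groups are equal; otherwise sizes differ
    by at most one, larger groups first.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")

    def score_of(s: DSBSite) -> float:
        if score_field in ("cleavage_score", "transcription_score"):
            return getattr(s, score_field)
        return s.scores[score_field]

    ranked = _sorted_desc(sites, score_of)
    n = len(ranked)
    base, rem = divmod(n, n_groups)
    sizes = [base + 1] * rem + [base] * (n_groups - rem)
    labels: dict[tuple[str, int], object] = {}
    scores: dict[tuple[str, int], float] = {}
    i = 0
    for g, size in enumerate(sizes):
        for s in ranked[i : i + size]:
            labels[genomic_key(s)] = g
            scores[genomic_key(s)] = score_of(s)
        i += size
    return SiteClassification(
        labels=labels,
        scores=scores,
        params=dict(score_field=score_field, n_groups=n_groups, sizes=sizes),
    )


def boxplot_stats(values) -> BoxplotStats:
    """Median, linear-interpolation quartiles, 1.5 x IQR whiskers, outliers."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(v[(v < lo_fence) | (v > hi_fence)]),
    )


def wilcoxon_ranksum(a, b, mode: str = "auto") -> GroupComparison:
    """Two-sided unpaired Mann-Whitney-Wilcoxon rank-sum test.

    mode 'exact' enumerates the permutation null (valid without ties),
    'normal_approx' uses the normal approximation with continuity and tie
    correction, and 'auto' picks exact when n_a + n_b <= 12 and the pooled
    data are tie-free.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (a.size + b.size <= 12 and not has_ties) else "normal_approx"
    if mode == "exact" and has_ties:
        mode = "normal_approx"  # exact enumeration is not valid under ties
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if method == "exact" else "normal_approx",
        n_a=int(a.size),
        n_b=int(b.size),
        summary_a=boxplot_stats(a),
        summary_b=boxplot_stats(b),
    )
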