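"""Cohort analysis of tandem-duplication burden versus two-gene expression.

Per-donor counts of small tandem duplications (< 100 kb, a signature of
break-induced-replication-like repair), a four-group expression
stratification on two genes, pairwise unpaired Wilcoxon comparisons, and a
negative-binomial regression testing whether one gene's effect on the TD
count depends on the other's expression (the interaction term).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dsb_classify import GroupComparison, wilcoxon_ranksum
from .synthetic import TD_TYPE

log = logging.getLogger(__name__)

GROUP_LABELS = {
    (True, True): "A_high/B_high",
    (True, False): "A_high/B_low",
    (False, True): "A_low/B_high",
    (False, False): "A_low/B_low",
}


@dataclass
class StratifiedCohort:
    """Four-group assignment of donors by high/low expression of two genes."""

    assignments: pd.DataFrame  # donor_id, A (bool high), B, group
    gene_a: str
    gene_b: str
    cutoff_a: float
    cutoff_b: float
    rule: str

    def donors_in(self, group: str) -> list[str]:
        df = self.assignments
        return df.loc[df["group"] == group, "donor_id"].tolist()


@dataclass
class NBFit:
    """Negative-binomial interaction fit: count ~ NB(exp(Xb), theta)."""

    beta: np.ndarray  # (b0, bA, bB, bAB) on the log scale
    se: np.ndarray
    theta: float  # NB2 size; variance = mu + mu^2/theta
    interaction_p: float  # two-sided Wald p for bAB
    converged: bool
    llf: float
    lrt_p: float | None = None


def count_td(sv_list, max_size: int = 100_000) -> int:
    """Number of tandem duplications strictly shorter than max_size.

    ``sv_list`` is an iterable of (sv_type, size); type matching is
    case-insensitive and accepts the common aliases 'TD' and 'DUP:TANDEM'.
    """
    aliases = {TD_TYPE, "td", "dup:tandem", "tandem-duplication"}
    n = 0
    for sv_type, size in sv_list:
        if str(sv_type).lower() in aliases and size < max_size:
            n += 1
    return n


def td_counts_per_donor(
    sv_df: pd.DataFrame, donor_ids=None, max_size: int = 100_000
) -> pd.Series:
    """Per-donor TD<max_size counts from a long SV table
    (donor_id, sv_type, size); donors absent from the table count zero."""
    grouped = sv_df.groupby("donor_id")[["sv_type", "size"]]
    counts = {
        did: count_td(zip(g["sv_type"], g["size"]), max_size)
        for did, g in grouped
    }
    if donor_ids is None:
        donor_ids = sorted(counts)
    return pd.Series([counts.get(d, 0) for d in donor_ids], index=list(donor_ids))


def stratify(
    expr_df: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    rule: str = "median",
    q: float | None = None,
    cutoffs: tuple[float, float] | None = None,
) -> StratifiedCohort:
    """Assign each donor to one of four groups by high/low expression.

    ``expr_df`` is long-format (donor_id, gene, value).  'high' means value
    strictly above the cutoff; donors exactly at the cutoff go to 'low'.
    rule: 'median' (per-gene sample median), 'quantile' (per-gene quantile
    q), or 'fixed' (explicit cutoffs).  Donors missing either gene are
    excluded with a logged count.
    """
    wide = expr_df.pivot_table(
        index="donor_id", columns="gene", values="value", aggfunc="first"
    )
    for g in (gene_a, gene_b):
        if g not in wide.columns:
            raise ValueError(f"gene {g!r} absent from expression table")
    complete = wide[[gene_a, gene_b]].dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        log.info("stratify: excluded %d donors missing expression", dropped)

    def cutoff_for(series: pd.Series, fixed: float | None) -> float:
        if rule == "median":
            c = float(series.median())
            if series.nunique() == 1:
                raise ValueError(
                    f"constant expression for a gene: median split degenerate"
                )
            return c
        if rule == "quantile":
            if q is None:
                raise ValueError("quantile rule requires q")
            return float(series.quantile(q))
        if rule == "fixed":
            if fixed is None:
                raise ValueError("fixed rule requires cutoffs")
            return float(fixed)
        raise ValueError(f"unknown cutoff rule {rule!r}")

    ca = cutoff_for(complete[gene_a], cutoffs[0] if cutoffs else None)
    cb = cutoff_for(complete[gene_b], cutoffs[1] if cutoffs else None)
    a = complete[gene_a] > ca
    b = complete[gene_b] > cb
    assignments = pd.DataFrame(
        {
            "donor_id": complete.index,
            "A": a.values,
            "B": b.values,
            "group": [GROUP_LABELS[(bool(x), bool(y))] for x, y in zip(a, b)],
        }
    ).reset_index(drop=True)
    return StratifiedCohort(
        assignments=assignments,
        gene_a=gene_a,
        gene_b=gene_b,
        cutoff_a=ca,
        cutoff_b=cb,
        rule=rule,
    )


def compare_groups(
    counts_by_group: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
) -> dict[tuple[str, str], GroupComparison]:
    """Unpaired two-sided Wilcoxon rank-sum per requested group pair."""
    out = {}
    for ga, gb in pairs:
        for g in (ga, gb):
            if g not in counts_by_group or len(counts_by_group[g]) == 0:
                raise ValueError(f"group {g!r} is empty or missing")
        out[(ga, gb)] = wilcoxon_ranksum(counts_by_group[ga], counts_by_group[gb])
    return out


def nb_interaction(counts, indicator_a, indicator_b, lrt: bool = False) -> NBFit:
    """Negative-binomial regression of counts on A, B and their interaction.

    Fits count ~ NB(mean = exp(b0 + b1 A + b2 B + b3 AB), size theta) by
    maximum likelihood (NB2 variance mu + mu^2/theta) and reports the
    two-sided Wald p-value for the interaction coefficient b3, which tests
    whether the effect of gene A on the TD burden depends on gene B.  With
    ``lrt=True`` a likelihood-ratio test against the no-interaction model is
    also computed.  Non-convergence is flagged, not silenced.
    """
    y = np.asarray(counts)
    a = np.asarray(indicator_a, dtype=float)
    b = np.asarray(indicator_b, dtype=float)
    if y.ndim != 1 or len(y) != len(a) or len(y) != len(b):
        raise ValueError("counts and indicators must be equal-length vectors")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if y.sum() == 0:
        raise ValueError("all counts are zero; the model is degenerate")
    cells = {(int(x), int(z)) for x, z in zip(a, b)}
    if len(cells) < 3:
        raise ValueError(
            f"design spans only {len(cells)} of 4 cells; interaction inestimable"
        )
    x = np.column_stack([np.ones_like(a), a, b, a * b])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y.astype(float), x, loglike_method="nb2")
        res = model.fit(disp=0, maxiter=200)
    converged = bool(res.mle_retvals.get("converged", False))
    alpha = float(res.params[-1])
    theta = np.inf if alpha <= 0 else 1.0 / alpha
    lrt_p = None
    if lrt:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            red = sm.NegativeBinomial(
                y.astype(float), x[:, :3], loglike_method="nb2"
            ).fit(disp=0, maxiter=200)
        from scipy import stats as sps

        stat = 2 * (res.llf - red.llf)
        lrt_p = float(sps.chi2.sf(max(stat, 0.0), df=1))
    return NBFit(
        beta=np.asarray(res.params[:4], dtype=float),
        se=np.asarray(res.bse[:4], dtype=float),
        theta=theta,
        interaction_p=float(res.pvalues[3]),
        converged=converged,
        llf=float(res.llf),
        lrt_p=lrt_p,
    )
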