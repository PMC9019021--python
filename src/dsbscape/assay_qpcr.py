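"""Deterministic Ct-table calculators for the qPCR-based assays.

Every calculator is parameterized by the per-cycle amplification efficiency
E (default 2, i.e. perfect doubling, which recovers the classic 2^-dCt
arithmetic) and exactly inverts the Ct forward model
Ct = ct_at_unit - log_E(quantity) at zero noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class AssayResult:
    """Replicate-level summary of one assay quantity."""

    name: str
    mean: float
    sem: float | None  # defined only for n >= 2
    n: int


def _check_efficiency(efficiency: float) -> None:
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1 (per-cycle amplification factor)")


def percent_input(
    ct_ip: float,
    ct_input: float,
    input_fraction: float = 1.0,
    efficiency: float = 2.0,
    input_is_total: bool = False,
) -> float:
    """ChIP efficiency as the percentage of input DNA immunoprecipitated.

    By default ct_input was measured on an aliquot comprising
    ``input_fraction`` of the chromatin used for the IP:

        % input = 100 * input_fraction * E**(ct_input - ct_ip)

    With ``input_is_total=True`` the input Ct already represents the full
    (undiluted-equivalent) chromatin and input_fraction is ignored in the
    dilution correction.
    """
    _check_efficiency(efficiency)
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    if input_is_total:
        return 100.0 * efficiency ** (ct_input - ct_ip)
    return 100.0 * input_fraction * efficiency ** (ct_input - ct_ip)


def normalized_enrichment(signal: float, reference: float) -> float:
    """Ratio of %input at a test locus to %input at a control locus (or of
    one factor to another); scale-free by construction."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return signal / reference


def ssdna_percent(
    ct_digested: float, ct_undigested: float, efficiency: float = 2.0
) -> float:
    """Resection readout: percent single-stranded DNA at a restriction site.

    Double-stranded templates are destroyed by the digest while ssDNA
    survives; with dCt = ct_digested - ct_undigested,

        % ssDNA = 100 / (E**(dCt - 1) + 0.5)

    All real dCt are accepted; values exceed 100 when dCt < 1 and are
    returned as-is (the caller decides how to flag them).
    """
    _check_efficiency(efficiency)
    dct = ct_digested - ct_undigested
    return 100.0 / (efficiency ** (dct - 1) + 0.5)


def cleavage_fraction(
    ct_site: float,
    ct_control_locus: float,
    ct_calibrator_site: float,
    ct_calibrator_control: float,
    efficiency: float = 2.0,
) -> float:
    """Relative cleavage by ddCt against a no-break control locus and a
    calibrator condition (e.g. the fully-induced 4 h time point).

    ddCt = (ct_site - ct_control) - (ct_calibrator_site - ct_calibrator_control)
    and the readout is E**(-ddCt): 1.0 means cleavage identical to the
    calibrator.  Run on a second induction round it quantifies repair
    fidelity — accurately repaired sites reconstitute the recognition
    sequence and are re-cut.
    """
    _check_efficiency(efficiency)
    ddct = (ct_site - ct_control_locus) - (ct_calibrator_site - ct_calibrator_control)
    return efficiency ** (-ddct)


def relative_quantity(
    ct_target: float, ct_reference: float, efficiency: float = 2.0
) -> float:
    """Quantity of the target relative to a reference amplicon:
    E**(ct_reference - ct_target).  Used for enrichment over a replication
    origin and for translocation-frequency quantification."""
    _check_efficiency(efficiency)
    return efficiency ** (ct_reference - ct_target)


def replicate_summary(values, name: str = "assay") -> AssayResult:
    """Mean and standard error over biological/technical replicates."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one replicate")
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size >= 2 else None
    return AssayResult(name=name, mean=float(v.mean()), sem=sem, n=int(v.size))


def paired_ttest(x, y) -> tuple[float, float]:
    """Two-sided paired t-test between matched condition vectors.

    Returns (t, p); with zero variance of the differences the statistic is
    undefined and (nan, nan) is returned — a degenerate comparison, not an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired test requires equal-length vectors")
    if np.ptp(x - y) == 0:
        return (float("nan"), float("nan"))
    res = stats.ttest_rel(x, y)
    return (float(res.statistic), float(res.pvalue))
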