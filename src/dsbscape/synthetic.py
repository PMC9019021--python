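"""Forward models generating every input class the pipeline consumes.

Reads pile up around planted cut sites under factor-specific kernels over a
uniform background; qPCR Ct values follow the exponential-amplification
model; cancer donors carry log-normal expression and negative-binomially
distributed tandem-duplication counts with a plantable two-gene interaction.
Every generator is a pure function of (parameters, seed).

The default toy genome is one 10 Mb contig: a scale model in which a 50 kb
plateau stands in for megabase-wide phospho-H2AX domains, while the kb-scale
exponential kernels (helicase/recombinase-like factors) keep their real
extent.  Shapes and relative widths, not absolute widths, are the properties
the downstream analyses test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec, toy_genome

TD_TYPE = "tandem_duplication"
DECOY_TYPES = ("deletion", "inversion", "insertion")


@dataclass(frozen=True)
class FactorKernel:
    """Spatial distribution of one factor's reads around a cut site.

    shape 'point' places reads at the cut (break-labeling signal);
    'exponential' decays symmetrically with scale decay_length_bp
    (helicase/recombinase-like spreading); 'plateau_with_dip' is flat out to
    plateau_halfwidth_bp with density reduced to dip_depth within
    dip_halfwidth_bp of the cut (broad phospho-histone domain with the
    central depletion).  Expected reads per site scale as
    amplitude * cleavage * transcription**transcription_coupling.
    """

    shape: str = "exponential"
    decay_length_bp: float = 2_000.0
    plateau_halfwidth_bp: float = 25_000.0
    dip_halfwidth_bp: float = 1_000.0
    dip_depth: float = 0.25
    amplitude: float = 1.0
    transcription_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("point", "exponential", "plateau_with_dip"):
            raise ValueError(f"unknown kernel shape {self.shape!r}")
        if self.decay_length_bp <= 0 or self.plateau_halfwidth_bp <= 0:
            raise ValueError("kernel lengths must be positive")
        if not 0 <= self.dip_halfwidth_bp < self.plateau_halfwidth_bp:
            raise ValueError("dip_halfwidth_bp must be in [0, plateau_halfwidth_bp)")
        if self.amplitude < 0 or self.transcription_coupling < 0:
            raise ValueError("amplitude and coupling must be >= 0")

    def sample_offsets(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n signed offsets from the kernel (distance then sign)."""
        if n == 0:
            return np.zeros(0)
        if self.shape == "point":
            dist = np.zeros(n)
        elif self.shape == "exponential":
            dist = rng.exponential(self.decay_length_bp, n)
        else:  # plateau_with_dip: piecewise-constant density, reduced in the dip
            w_in = self.dip_depth * self.dip_halfwidth_bp
            w_out = self.plateau_halfwidth_bp - self.dip_halfwidth_bp
            p_in = w_in / (w_in + w_out)
            inside = rng.random(n) < p_in
            dist = np.where(
                inside,
                rng.uniform(0, self.dip_halfwidth_bp, n),
                rng.uniform(self.dip_halfwidth_bp, self.plateau_halfwidth_bp, n),
            )
        sign = rng.integers(0, 2, n) * 2 - 1
        return (dist * sign).round()


def make_sites(
    genome: GenomeSpec | None = None,
    n_sites: int = 100,
    min_gap: int = 50_000,
    seed: int = 0,
):
    """Place n_sites cut positions with pairwise gaps >= min_gap.

    Each site carries a planted cleavage grade (linearly spaced on
    [0.1, 1], then shuffled — so "top N by cleavage" is well defined) and a
    log-normal(0, 1) transcription level.  Deterministic per seed; an
    infeasible packing raises rather than silently truncating.
    """
    from .dsb_signal import DSBSite

    if genome is None:
        genome = toy_genome()
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_sites * min_gap >= genome.total_length:
        raise ValueError(
            f"cannot place {n_sites} sites with gap {min_gap} in a "
            f"{genome.total_length} bp genome"
        )
    rng = np.random.default_rng(seed)
    lengths = np.array([ln for _, ln in genome.contigs], dtype=float)
    names = [nm for nm, _ in genome.contigs]

    for _ in range(100):
        alloc = rng.multinomial(n_sites, lengths / lengths.sum())
        if all(
            (a - 1) * min_gap < ln for a, ln in zip(alloc, lengths) if a > 0
        ) and all(a == 0 or ln > (a - 1) * min_gap + 1 for a, ln in zip(alloc, lengths)):
            break
    else:
        raise ValueError("could not allocate sites to contigs under min_gap")

    positions: list[tuple[str, int]] = []
    for name, length, count in zip(names, lengths, alloc):
        if count == 0:
            continue
        slack = length - (count - 1) * min_gap
        u = np.sort(rng.uniform(0, slack, count))
        pos = (u + np.arange(count) * min_gap).astype(int)
        positions.extend((name, int(p)) for p in pos)

    cleavage = rng.permutation(np.linspace(0.1, 1.0, n_sites))
    transcription = rng.lognormal(0.0, 1.0, n_sites)
    return [
        DSBSite(
            contig=c,
            position=p,
            cleavage_score=float(cl),
            transcription_score=float(t),
        )
        for (c, p), cl, t in zip(positions, cleavage, transcription)
    ]


def _site_weights(
    sites, kernel: FactorKernel, site_amplitudes=None, site_weights=None
) -> np.ndarray:
    if site_weights is not None:
        return np.asarray(site_weights, dtype=float)
    amps = (
        np.full(len(sites), kernel.amplitude)
        if site_amplitudes is None
        else np.asarray(site_amplitudes, dtype=float)
    )
    cleav = np.array([s.cleavage_score for s in sites])
    trans = np.array([s.transcription_score for s in sites])
    return amps * cleav * trans**kernel.transcription_coupling


def simulate_reads(
    sites,
    kernel: FactorKernel,
    genome: GenomeSpec | None = None,
    background_rate: float = 0.0,
    total_reads: int = 100_000,
    read_len: int = 50,
    seed: int = 0,
    site_amplitudes=None,
    site_weights=None,
):
    """Draw exactly total_reads single-end reads: background + site kernels.

    The read set is a multinomial mixture: a uniform background component
    with weight background_rate * genome length, and one component per site
    with weight amplitude * cleavage * transcription**coupling whose
    positions follow the kernel.  ``site_amplitudes`` replaces the scalar
    amplitude per site (cleavage/transcription scaling retained);
    ``site_weights`` overrides the full per-site mixture weight.  Kernel
    tails extending past a contig edge are clipped to the contig (count
    preserved).  Strand is uniform; output is coordinate-sorted.
    """
    from .signal_io import ReadRecord

    if genome is None:
        genome = toy_genome()
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    rng = np.random.default_rng(seed)

    site_w = _site_weights(sites, kernel, site_amplitudes, site_weights)
    bg_w = background_rate * genome.total_length
    weights = np.concatenate([[bg_w], site_w])
    if weights.sum() <= 0:
        raise ValueError("all mixture weights are zero")
    counts = rng.multinomial(total_reads, weights / weights.sum())

    lengths = dict(genome.contigs)
    offsets = np.concatenate(
        [[0], np.cumsum([ln for _, ln in genome.contigs])]
    )
    reads: list[ReadRecord] = []

    # background: uniform over the concatenated genome
    if counts[0]:
        flat = rng.uniform(0, genome.total_length, counts[0])
        idx = np.searchsorted(offsets, flat, side="right") - 1
        for i, f in zip(idx, flat):
            contig, length = genome.contigs[i]
            start = int(min(f - offsets[i], length - read_len))
            start = max(start, 0)
            strand = "+" if rng.integers(0, 2) else "-"
            reads.append(ReadRecord(contig, start, min(start + read_len, length), strand))

    for site, k in zip(sites, counts[1:]):
        if k == 0:
            continue
        length = lengths[site.contig]
        pos = site.position + kernel.sample_offsets(int(k), rng)
        pos = np.clip(pos, 0, length - read_len).astype(int)
        strands = rng.integers(0, 2, int(k))
        for p, st in zip(pos, strands):
            reads.append(
                ReadRecord(site.contig, int(p), int(p) + read_len, "+" if st else "-")
            )

    reads.sort(key=lambda r: (r.contig, r.start, r.strand))
    return reads


def simulate_correlated_tracks(
    sites,
    base_kernel: FactorKernel,
    target_pearson: float,
    genome: GenomeSpec | None = None,
    total_reads: int = 200_000,
    background_rate: float = 0.0,
    amplitude_sigma: float = 0.5,
    read_len: int = 50,
    seed: int = 0,
):
    """Two read sets whose per-site amplitudes share population correlation r.

    Per-site amplitudes are amplitude * exp(amplitude_sigma * z) with
    (z1, z2) bivariate standard normal at correlation target_pearson (a
    Gaussian copula on log-amplitudes); r=1 makes the two amplitude vectors
    identical.  The amplitude pair is the *entire* per-site weight here —
    cleavage/transcription scaling is deliberately bypassed so the planted
    correlation is the only site-level association shared by the two tracks.
    """
    if not -1 <= target_pearson <= 1:
        raise ValueError("target_pearson must be in [-1, 1]")
    ss = np.random.SeedSequence(seed)
    s_amp, s_a, s_b = ss.spawn(3)
    rng = np.random.default_rng(s_amp)
    if abs(target_pearson) == 1.0:
        z1 = rng.standard_normal(len(sites))
        z = np.column_stack([z1, np.copysign(1.0, target_pearson) * z1])
    else:
        cov = np.array([[1.0, target_pearson], [target_pearson, 1.0]])
        z = rng.multivariate_normal(
            np.zeros(2), cov, size=len(sites), method="cholesky"
        )
    amp_a = base_kernel.amplitude * np.exp(amplitude_sigma * z[:, 0])
    amp_b = base_kernel.amplitude * np.exp(amplitude_sigma * z[:, 1])
    common = dict(
        kernel=base_kernel,
        genome=genome,
        background_rate=background_rate,
        total_reads=total_reads,
        read_len=read_len,
    )
    reads_a = simulate_reads(
        sites, seed=int(s_a.generate_state(1)[0] % 2**31), site_weights=amp_a, **common
    )
    reads_b = simulate_reads(
        sites, seed=int(s_b.generate_state(1)[0] % 2**31), site_weights=amp_b, **common
    )
    return reads_a, reads_b


def simulate_qpcr(
    true_quantities,
    efficiency: float = 2.0,
    ct_at_unit: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ct table from planted quantities: Ct = ct_at_unit - log_E(q) + noise.

    ``labels``, if given, supplies sample/target/condition/replicate columns
    matching the quantities row-for-row; defaults are filled otherwise.
    Quantities must be positive; efficiency in (1, 2].
    """
    q = np.asarray(true_quantities, dtype=float)
    if np.any(q <= 0):
        raise ValueError("quantities must be positive")
    if not 1 < efficiency <= 2:
        raise ValueError("efficiency must be in (1, 2]")
    rng = np.random.default_rng(seed)
    ct = ct_at_unit - np.log(q) / np.log(efficiency)
    if noise_sd > 0:
        ct = ct + rng.normal(0, noise_sd, len(q))
    if labels is None:
        labels = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(len(q))],
                "target": "amplicon",
                "condition": "na",
                "replicate": 1,
            }
        )
    out = labels.copy().reset_index(drop=True)
    out["ct"] = ct
    return out


def simulate_donors(
    n_donors: int,
    beta: tuple[float, float, float, float] = (np.log(5), 0.0, 0.0, np.log(2)),
    dispersion: float = 10.0,
    expr_sigma: float = 1.0,
    genes: tuple[str, str] = ("SETX", "POLD3"),
    n_decoys: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort with a planted two-gene interaction on tandem-duplication counts.

    Expression for each gene is log-normal(0, expr_sigma); the high/low
    indicators A, B are the sample-median split (> median is high, the same
    rule the stratifier applies, so labels round-trip).  TD counts are
    NB(mean = exp(b0 + b1 A + b2 B + b3 AB), size = dispersion); dispersion
    may be np.inf for the Poisson limit.  The SV list holds exactly that many
    tandem duplications with sizes < 100 kb plus n_decoys per-donor decoys
    (other SV types, or TDs >= 100 kb) that the size/type filter must reject.

    Returns (expression table: donor_id, gene, value;
             SV table: donor_id, sv_type, size).
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    expr = rng.lognormal(0.0, expr_sigma, size=(n_donors, 2))
    a = expr[:, 0] > np.median(expr[:, 0])
    b = expr[:, 1] > np.median(expr[:, 1])
    b0, b1, b2, b3 = beta
    mu = np.exp(b0 + b1 * a + b2 * b + b3 * (a & b))
    if np.isinf(dispersion):
        counts = rng.poisson(mu)
    else:
        counts = rng.negative_binomial(dispersion, dispersion / (dispersion + mu))

    donor_ids = [f"D{i:04d}" for i in range(n_donors)]
    expr_df = pd.DataFrame(
        {
            "donor_id": np.repeat(donor_ids, 2),
            "gene": list(genes) * n_donors,
            "value": expr.ravel(),
        }
    )
    rows = []
    for did, c in zip(donor_ids, counts):
        for _ in range(int(c)):
            rows.append((did, TD_TYPE, int(rng.integers(1_000, 100_000))))
        for _ in range(n_decoys):
            if rng.random() < 0.5:
                rows.append((did, TD_TYPE, int(rng.integers(100_000, 1_000_000))))
            else:
                rows.append(
                    (
                        did,
                        DECOY_TYPES[rng.integers(0, len(DECOY_TYPES))],
                        int(rng.integers(1_000, 500_000)),
                    )
                )
    sv_df = pd.DataFrame(rows, columns=["donor_id", "sv_type", "size"])
    return expr_df, sv_df
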