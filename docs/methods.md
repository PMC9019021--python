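# Methods

## The problem

Sequence-defined DNA double-strand breaks (DSBs) — e.g. from a
restriction enzyme activated at annotated genomic sites — let one ask
quantitative questions about repair: which factors accumulate around the
cut, over what distance, how recruitment depends on the transcriptional
state of the locus, and what genomic scars (small tandem duplications) a
given repair route leaves in tumor genomes. `dsbscape` implements the
computational layer of such a study as a reusable pipeline: coverage
normalization, site-anchored quantification, classification statistics,
qPCR assay arithmetic, and a cohort-level count regression — together with
forward models that generate every input class, so the entire pipeline is
testable with no external data.

## Signal model and conventions

Reads are single-end intervals; coverage counts **read starts** per bin
(default 100 bp). This makes a windowed sum an exact read count, so the
"normalized number of reads in a window" statistics are exact under CPM
scaling (bin × 10⁶ / total reads; the genome-wide sum of a CPM track is
10⁶ by construction). Per-base pileup or fragment extension would change
windowed sums into fractional quantities; read-start counting is the
declared convention. Coordinates are 0-based half-open throughout; SAM
input is converted on read. Duplicate removal collapses reads sharing
(contig, 5′ start, strand), mirroring single-end PCR-duplicate removal.

A "window of W" always means the full span [position − W/2, position +
W/2), half-open, centered on the cut. Site-by-position matrices require W
to be a multiple of the bin size so row sums of interior sites equal the
corresponding windowed sums exactly. Cells clipped at contig edges are
missing (NaN) and excluded from column means rather than zero-filled,
which would fabricate dips at profile edges.

`spread_width` reports the width of the contiguous region around the peak
that stays above background + fraction × (peak − background), with
background estimated from the outermost 10% of bins per side; a profile
with no peak above background returns None (undefined, deliberately not
zero). For a symmetric exponential kernel of scale λ this width at
fraction 0.5 is 2λ ln 2 (≈2.77 kb at λ = 2 kb), which the simulations
reproduce. `fit_decay_length` regresses log background-subtracted signal
on |offset| over the flanks; binning induces a small (≲10%) downward bias
at 100 bp bins, well inside the 20% recovery tolerance the design targets.

## Classification statistics

Site ranking is always descending on the score with ties broken by
(contig, position), making every classification invariant to input order.
The enrichment-ratio classifier scores each site as
(factor signal in 4 kb + pseudocount) / (cleavage signal in 1 kb +
pseudocount); the top and bottom 20 of the ranking are the "high" and
"low" recruitment classes. The pseudocount (default 1 CPM unit) guards
weakly cleaved sites; ratios are computed on CPM values by default.
Quantile groups split the ranked sites into contiguous blocks (sizes
differing by at most one, larger first), reproducing four groups of 20
from an 80-site catalog.

Group comparisons use the unpaired two-sided Wilcoxon rank-sum test. The
compared site subsets are distinct groups of equal size with no natural
pairing, so the unpaired test is the default; a paired alternative exists
for matched designs. Exact p-values are computed by enumeration when
n₁ + n₂ ≤ 12 and the pooled sample is tie-free, otherwise the normal
approximation with continuity and tie correction is used (`auto` picks
accordingly; the implementation delegates to
`scipy.stats.mannwhitneyu`, and the test suite verifies exact p against
full labeling enumeration for every group-size pair up to 6 + 6).
Boxplot summaries use linear-interpolation quartiles and the 1.5 × IQR
fence convention: whiskers at the extreme values inside the fences,
everything outside flagged as an outlier.

## qPCR calculators

All assay arithmetic is parameterized by the per-cycle amplification
efficiency E (default 2) and inverts the forward model
Ct = Ct(1 unit) − log_E(quantity) exactly at zero noise:

- percent input: 100 × input_fraction × E^(Ct_input − Ct_IP);
- resection ssDNA%: 100 / (E^(ΔCt − 1) + 0.5) with ΔCt = digested −
  undigested (the established restriction-protection formula; values
  exceed 100 for ΔCt < 1 and are reported as-is);
- cleavage / repair-fidelity: E^(−ΔΔCt) against a no-break control locus
  and a calibrator condition;
- relative quantity (origin-normalized enrichment, translocation
  frequency): E^(Ct_ref − Ct_target).

Replicate summaries report mean and SEM (sd/√n, n ≥ 2); matched
condition vectors are compared with a paired two-sided t-test, which is
the replicate-level test, distinct from the rank test used for genomic
site groups.

## Cohort analysis

Per donor, the tandem-duplication burden is the number of SVs of TD type
strictly shorter than 100 kb. Donors are stratified into four groups by
high/low expression of two genes; because no cutoff rule is canonical,
median split per gene is the default (strictly above the cutoff is
"high"; values at the cutoff go low), with quantile and fixed-threshold
alternatives. The interaction model is an NB2 negative-binomial
regression, count ~ NB(exp(β₀ + β₁A + β₂B + β₃AB), θ), fitted by maximum
likelihood with a two-sided Wald test on β₃ (likelihood-ratio test
optional). θ is reported as the NB size (variance μ + μ²/θ). The fit
reduces to Poisson regression as θ → ∞ (checked against an independent
Poisson fit) and the optimizer's log-likelihood is verified to dominate
the likelihood at the planted truth on simulated data.

## What the forward models emulate — and what they do not

The toy genome is one 10 Mb contig: a scale model. Kilobase-scale
exponential kernels (helicase/recombinase-like factors, default λ = 2 kb;
a "late" condition uses λ = 8 kb to model progressive spreading) keep
their real extent, while the broad phospho-histone domain is a 50 kb
plateau with a central dip standing in for megabase-wide domains —
shapes and relative widths, not absolute widths, are the tested
properties. Sites carry planted cleavage grades (linearly spaced, then
shuffled, so "top N by cleavage" is exact) and log-normal(0, 1)
transcription levels; per-site expected read counts scale as amplitude ×
cleavage × transcription^coupling over a uniform background, with read
totals fixed by a multinomial draw (count conservation is exact). The
correlated-track generator plants a Gaussian-copula correlation on
log-amplitudes and deliberately bypasses the shared cleavage/transcription
scaling, so the planted r is the only association between the two tracks.

The models do not emulate sequence content, mappability, GC or chromatin
biases, fragment-length structure, or aligner artifacts; passing recovery
tests therefore demonstrates the correctness of the estimators under the
assumed generative structure, not robustness to real-data biases.
Likewise the donor generator produces clean log-normal expression and a
pure four-cell NB design without covariates, batch structure, or
expression–count confounding beyond the planted interaction.

Null cohorts for the type-I calibration use 200 donors, matching the
scale of the real pancreatic cohort the analysis design targets
(76 + 41 + 41 + 37 donors). At this size the ML-dispersion Wald test is
mildly liberal (empirical level ≈ 0.06 at nominal 0.05), which the
calibration band accommodates. Per-cohort seeds are spawned from a
`numpy` SeedSequence rather than taken as consecutive integers;
consecutive seeding produced measurably super-binomial batch variance in
rejection rates.

## Problem sizes

Recovery analyses run at the catalog sizes the design statements use: 80
analysed sites from 100-site catalogs, 10⁵–2×10⁵ reads per track, 2000
donors for interaction-coefficient recovery, 500 null cohorts of 200
donors for calibration. The full test suite runs in about half a minute;
the acceptance script in about fifteen seconds.

## Known limitations

- bedGraph metadata (bin size, totals, contig lengths) travels in
  comment lines; third-party bedGraphs need the genome and bin size
  supplied explicitly, and intervals must align to the bin grid.
- `site_matrix` requires the matrix bin to equal the track bin; no
  resampling is performed.
- The exact Wilcoxon path refuses tied data (falls back to the corrected
  normal approximation) rather than enumerating a tie-adjusted null.
- `spread_width` measures the contiguous above-threshold region
  containing the peak; a kernel with a deep central dip reports the width
  of one shoulder, not the full domain span.
- BAM/bigWig binary codecs are not part of the core contract; text SAM
  and bedGraph are.
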