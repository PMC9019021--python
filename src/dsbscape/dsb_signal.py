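"""Site-anchored signal quantification around DSB cut positions.

Windows are full widths centered on the cut coordinate: a "window of W"
always spans [position - W/2, position + W/2), half-open.  Cells clipped at
contig edges are missing (NaN) and excluded from column means, never
zero-filled, to avoid artificial dips at the ends of profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signal_io import SignalTrack


@dataclass
class DSBSite:
    """An annotated double-strand-break position.

    cleavage_score holds the break-labeling (BLESS-like) windowed count used
    for top-N selection and heatmap ordering; transcription_score holds the
    pre-damage RNA polymerase II occupancy; scores carries any additional
    per-factor windowed values by name.
    """

    contig: str
    position: int
    cleavage_score: float = 0.0
    transcription_score: float = 0.0
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")


def genomic_key(site: DSBSite) -> tuple[str, int]:
    return (site.contig, site.position)


def write_sites_bed(sites: list["DSBSite"], path) -> None:
    """Site catalog as BED: 1 bp feature at the cut, score = cleavage,
    extra columns for transcription and named per-factor scores."""
    with open(path, "w") as fh:
        for s in sites:
            extra = ";".join(f"{k}={v:.6g}" for k, v in sorted(s.scores.items()))
            fh.write(
                f"{s.contig}\t{s.position}\t{s.position + 1}\tDSB\t"
                f"{s.cleavage_score:.6g}\t+\t{s.transcription_score:.6g}\t{extra}\n"
            )


def read_sites_bed(path) -> list["DSBSite"]:
    """Inverse of :func:`write_sites_bed`."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            scores = {}
            if len(f) >= 8 and f[7]:
                for item in f[7].split(";"):
                    k, _, v = item.partition("=")
                    scores[k] = float(v)
            sites.append(
                DSBSite(
                    contig=f[0],
                    position=int(f[1]),
                    cleavage_score=float(f[4]) if len(f) >= 5 else 0.0,
                    transcription_score=float(f[6]) if len(f) >= 7 else 0.0,
                    scores=scores,
                )
            )
    return sites


@dataclass
class SiteSignalMatrix:
    """sites x positional-bins matrix; the substrate of profiles and heatmaps."""

    sites: list[DSBSite]
    window: int  # full width, bp
    bin_size: int
    values: np.ndarray  # shape (n_sites, window // bin_size); NaN = clipped

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sites), self.window // self.bin_size):
            raise ValueError("matrix shape inconsistent with sites/window/bin")

    @property
    def offsets(self) -> np.ndarray:
        """Nominal bin-start offsets relative to the cut position, in bp.

        Exact for sites aligned to the bin grid; off-grid sites shift by less
        than one bin.
        """
        k = self.values.shape[1]
        first = math.ceil(-self.window / 2 / self.bin_size) * self.bin_size
        return first + np.arange(k) * self.bin_size


def _window_bins(position: int, window: int, bin_size: int) -> tuple[int, int]:
    """Bin index range [b0, b1) whose bin starts fall in the centered window."""
    lo = position - window / 2
    hi = position + window / 2
    b0 = math.ceil(lo / bin_size)
    b1 = math.ceil(hi / bin_size)
    return b0, b1


def window_sum(track: SignalTrack, site: DSBSite, window: int) -> float:
    """Sum of bin values whose bin start lies within the centered window.

    With read-start coverage this is exactly the (possibly CPM-scaled) number
    of reads starting in the window.  Windows are clipped at contig edges.
    """
    if window < track.bin_size:
        raise ValueError("window must be >= bin_size")
    if site.contig not in track.data:
        raise ValueError(f"site contig {site.contig!r} not in track")
    if site.position >= track.contig_lengths[site.contig]:
        raise ValueError(f"site {genomic_key(site)} beyond contig end")
    values = track.data[site.contig]
    b0, b1 = _window_bins(site.position, window, track.bin_size)
    b0 = max(b0, 0)
    b1 = min(b1, len(values))
    return float(values[b0:b1].sum())


def site_matrix(
    track: SignalTrack,
    sites: list[DSBSite],
    window: int,
    bin_size: int | None = None,
) -> SiteSignalMatrix:
    """Assemble the sites x bins matrix of binned signal around each site.

    ``window`` must be a multiple of the track bin size so every row has the
    same number of columns and row-sums of interior sites equal
    :func:`window_sum`.  Edge-clipped cells are NaN.
    """
    if bin_size is None:
        bin_size = track.bin_size
    if bin_size != track.bin_size:
        raise ValueError(
            f"matrix bin ({bin_size}) must equal track bin ({track.bin_size})"
        )
    if window % bin_size:
        raise ValueError("window must be a multiple of bin_size")
    k = window // bin_size
    out = np.full((len(sites), k), np.nan)
    for i, site in enumerate(sites):
        if site.contig not in track.data:
            raise ValueError(f"site contig {site.contig!r} not in track")
        values = track.data[site.contig]
        b0, _ = _window_bins(site.position, window, bin_size)
        src0 = max(b0, 0)
        src1 = min(b0 + k, len(values))
        if src1 > src0:
            out[i, src0 - b0 : src1 - b0] = values[src0:src1]
    return SiteSignalMatrix(sites=list(sites), window=window, bin_size=bin_size, values=out)


def average_profile(matrix: SiteSignalMatrix) -> np.ndarray:
    """Column-wise mean over non-missing cells — the aggregate metaprofile."""
    if not matrix.sites:
        raise ValueError("matrix has no sites")
    with np.errstate(invalid="ignore"):
        return np.nanmean(matrix.values, axis=0)


def order_by_cleavage(matrix: SiteSignalMatrix) -> SiteSignalMatrix:
    """Sort rows by cleavage_score descending (heatmap ordering).

    Ties resolve by (contig, position) ascending, so the ordering is a pure
    function of the sites, not of input order.
    """
    order = sorted(
        range(len(matrix.sites)),
        key=lambda i: (-matrix.sites[i].cleavage_score, genomic_key(matrix.sites[i])),
    )
    return SiteSignalMatrix(
        sites=[matrix.sites[i] for i in order],
        window=matrix.window,
        bin_size=matrix.bin_size,
        values=matrix.values[order],
    )


def pearson(x, y) -> float:
    """Sample Pearson correlation of two equal-length per-site vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def fit_decay_length(
    profile: np.ndarray, offsets: np.ndarray, max_offset: float | None = None
) -> float:
    """Exponential decay length (bp) from a metaprofile's flanks.

    Subtracts the edge background (outermost 10% of bins per side), then
    regresses log signal on |offset| over flank bins with positive
    background-subtracted signal, excluding the central bin; the decay
    length is -1/slope.  ``max_offset`` restricts the fit range (useful to
    stay above the noise floor).
    """
    profile = np.asarray(profile, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    n = len(profile)
    edge = max(1, n // 10)
    background = float(np.nanmean(np.concatenate([profile[:edge], profile[-edge:]])))
    signal = profile - background
    absoff = np.abs(offsets)
    mask = (signal > 0) & (absoff > 0) & np.isfinite(signal)
    if max_offset is not None:
        mask &= absoff <= max_offset
    if mask.sum() < 3:
        raise ValueError("too few flank bins above background to fit a decay")
    slope = np.polyfit(absoff[mask], np.log(signal[mask]), 1)[0]
    if slope >= 0:
        raise ValueError("profile flanks do not decay")
    return float(-1.0 / slope)


def spread_width(
    profile: np.ndarray, bin_size: int, fraction: float = 0.5
) -> float | None:
    """Width (bp) of the central region above ``fraction`` of the peak height.

    Background is the mean of the outermost 10% of bins on each side; height
    is measured above background.  Returns None when no bin rises above
    background (undefined, deliberately not zero).
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if n < 4:
        raise ValueError("profile too short")
    edge = max(1, n // 10)
    finite = np.isfinite(profile)
    if not finite.any():
        return None
    bg_bins = np.concatenate([profile[:edge], profile[-edge:]])
    background = float(np.nanmean(bg_bins))
    peak_idx = int(np.nanargmax(profile))
    height = profile[peak_idx] - background
    if not np.isfinite(height) or height <= 0:
        return None
    threshold = background + fraction * height
    above = profile >= threshold
    # contiguous run containing the peak
    lo = peak_idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi < n - 1 and above[hi + 1]:
        hi += 1
    return float((hi - lo + 1) * bin_size)
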