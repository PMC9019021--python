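"""Alignment/coverage I/O: read SAM/BED reads, deduplicate, bin into CPM tracks.

Coordinates are 0-based half-open (BED convention) everywhere; SAM's 1-based
positions are converted on read.  Coverage counts read *starts* per bin, so
windowed sums downstream are exact read counts.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pysam

from .genome import GenomeSpec

log = logging.getLogger(__name__)

CPM_TOTAL = 1_000_000.0


class ReadRecord(NamedTuple):
    """One aligned single-end read as a genomic interval."""

    contig: str
    start: int  # 0-based
    end: int    # half-open
    strand: str  # '+' or '-'


@dataclass
class SignalTrack:
    """Binned genome-wide signal, optionally CPM-normalized.

    ``data[contig]`` has ``ceil(contig_length / bin_size)`` entries; the last
    bin may cover a partial window at the contig end.
    """

    bin_size: int
    contig_lengths: dict[str, int]
    data: dict[str, np.ndarray] = field(default_factory=dict)
    normalized: bool = False
    total_reads: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for name, length in self.contig_lengths.items():
            n_bins = math.ceil(length / self.bin_size)
            if name not in self.data:
                self.data[name] = np.zeros(n_bins)
            elif len(self.data[name]) != n_bins:
                raise ValueError(
                    f"{name}: expected {n_bins} bins, got {len(self.data[name])}"
                )

    def sum(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            bin_size=self.bin_size,
            contig_lengths=dict(self.contig_lengths),
            data={k: v.copy() for k, v in self.data.items()},
            normalized=self.normalized,
            total_reads=self.total_reads,
        )


def _validate_read(rec: ReadRecord, lengths: dict[str, int] | None) -> None:
    if rec.start < 0 or rec.end <= rec.start:
        raise ValueError(f"invalid interval {rec}")
    if lengths is not None:
        if rec.contig not in lengths:
            raise ValueError(f"unknown contig {rec.contig!r}")
        if rec.end > lengths[rec.contig]:
            raise ValueError(
                f"read end {rec.end} beyond contig {rec.contig} "
                f"length {lengths[rec.contig]}"
            )


def read_reads(
    path: str | os.PathLike,
    format: str | None = None,
    genome: GenomeSpec | None = None,
) -> list[ReadRecord]:
    """Read aligned single-end reads from a SAM or BED6 file.

    Unmapped SAM records and malformed BED lines are skipped with a logged
    tally.  A record on an unknown contig or extending past the contig end is
    an error.  An empty file yields an empty list.
    """
    path = os.fspath(path)
    if format is None:
        format = "SAM" if path.endswith(".sam") else "BED"
    fmt = format.upper()
    lengths = dict(genome.contigs) if genome is not None else None

    reads: list[ReadRecord] = []
    skipped = 0
    if fmt == "SAM":
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            if lengths is None and sam.header.get("SQ"):
                lengths = {sq["SN"]: sq["LN"] for sq in sam.header["SQ"]}
            for aln in sam:
                if aln.is_unmapped:
                    skipped += 1
                    continue
                rec = ReadRecord(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                )
                _validate_read(rec, lengths)
                reads.append(rec)
    elif fmt == "BED":
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    skipped += 1
                    continue
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    skipped += 1
                    continue
                strand = fields[5] if len(fields) >= 6 else "+"
                rec = ReadRecord(fields[0], start, end, strand)
                _validate_read(rec, lengths)
                reads.append(rec)
    else:
        raise ValueError(f"unsupported format {format!r}")
    if skipped:
        log.info("read_reads: skipped %d unmapped/malformed records", skipped)
    return reads


def write_reads_bed(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    """Write reads as BED6 (0-based half-open), one line per read."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}\n")


def write_reads_sam(
    reads: Iterable[ReadRecord], genome: GenomeSpec, path: str | os.PathLike
) -> None:
    """Write reads as a minimal mapped single-end SAM (header + records).

    No sequence bases are emulated: SEQ/QUAL are '*' and the CIGAR is a full
    match of the read length.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in genome.contigs],
        }
    )
    with pysam.AlignmentFile(os.fspath(path), "wh", header=header) as out:
        for i, r in enumerate(reads):
            aln = pysam.AlignedSegment(header)
            aln.query_name = f"r{i}"
            aln.reference_name = r.contig
            aln.reference_start = r.start
            aln.cigarstring = f"{r.end - r.start}M"
            aln.mapping_quality = 60
            aln.flag = 16 if r.strand == "-" else 0
            out.write(aln)


def deduplicate(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Keep at most one read per (contig, start, strand), preserving order.

    This mirrors single-end PCR-duplicate removal: reads with the same 5'
    position on the same strand are collapsed.  Idempotent.
    """
    seen: set[tuple[str, int, str]] = set()
    out = []
    for r in reads:
        key = (r.contig, r.start, r.strand)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def coverage(
    reads: Iterable[ReadRecord], genome: GenomeSpec, bin_size: int = 100
) -> SignalTrack:
    """Raw binned coverage: each bin counts the reads whose start lies in it.

    The genome-wide sum therefore equals the number of reads exactly.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    lengths = dict(genome.contigs)
    track = SignalTrack(bin_size=bin_size, contig_lengths=lengths)
    n = 0
    by_contig: dict[str, list[int]] = {}
    for r in reads:
        if r.contig not in lengths:
            raise ValueError(f"unknown contig {r.contig!r}")
        by_contig.setdefault(r.contig, []).append(r.start)
        n += 1
    for contig, starts in by_contig.items():
        idx = np.asarray(starts) // bin_size
        track.data[contig] = np.bincount(
            idx, minlength=len(track.data[contig])
        ).astype(float)
    track.total_reads = n
    return track


def cpm_normalize(track: SignalTrack) -> SignalTrack:
    """Counts-per-million scaling: bin * 1e6 / total_reads.

    The genome-wide sum of a track built from whole-genome reads becomes 1e6.
    Normalizing an already-normalized track is an error (not idempotent by
    design: doing it twice silently would corrupt the scale).
    """
    if track.normalized:
        raise ValueError("track is already CPM-normalized")
    if track.total_reads <= 0:
        raise ValueError("cannot CPM-normalize a track with zero reads")
    out = track.copy()
    scale = CPM_TOTAL / track.total_reads
    for contig in out.data:
        out.data[contig] = out.data[contig] * scale
    out.normalized = True
    return out


def write_bedgraph(track: SignalTrack, path: str | os.PathLike) -> None:
    """Write a track as bedGraph with dsbscape metadata comments.

    Zero-valued runs are omitted; consecutive equal-valued bins are merged.
    Values are written with 6 significant digits (the round-trip tolerance).
    """
    with open(path, "w") as fh:
        fh.write(f"# dsbscape bin_size={track.bin_size}\n")
        fh.write(f"# dsbscape total_reads={track.total_reads}\n")
        fh.write(f"# dsbscape normalized={int(track.normalized)}\n")
        for name, length in track.contig_lengths.items():
            fh.write(f"# dsbscape contig={name}:{length}\n")
        fh.write('track type=bedGraph name="dsbscape"\n')
        for contig, values in track.data.items():
            length = track.contig_lengths[contig]
            i = 0
            nb = len(values)
            while i < nb:
                v = values[i]
                j = i + 1
                while j < nb and values[j] == v:
                    j += 1
                if v != 0:
                    start = i * track.bin_size
                    end = min(j * track.bin_size, length)
                    fh.write(f"{contig}\t{start}\t{end}\t{v:.6g}\n")
                i = j


def read_bedgraph(
    path: str | os.PathLike,
    genome: GenomeSpec | None = None,
    bin_size: int | None = None,
) -> SignalTrack:
    """Read a bedGraph into a SignalTrack; inverse of :func:`write_bedgraph`.

    dsbscape metadata comments supply bin size, totals and contig lengths;
    for third-party files pass ``genome`` and ``bin_size`` explicitly.
    Intervals must align to the bin grid; overlapping intervals are an error.
    """
    meta: dict[str, str] = {}
    contig_lengths: dict[str, int] = {}
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# dsbscape "):
                key, _, val = line[len("# dsbscape "):].partition("=")
                if key == "contig":
                    name, _, ln = val.partition(":")
                    contig_lengths[name] = int(ln)
                else:
                    meta[key] = val
                continue
            if not line or line.startswith(("track", "browser", "#")):
                continue
            c, s, e, v = line.split("\t")
            rows.append((c, int(s), int(e), float(v)))

    if genome is not None:
        contig_lengths = dict(genome.contigs)
    if bin_size is None:
        if "bin_size" not in meta:
            raise ValueError("bin_size not in file metadata; pass bin_size=")
        bin_size = int(meta["bin_size"])
    if not contig_lengths:
        raise ValueError("contig lengths unknown; pass genome=")

    track = SignalTrack(
        bin_size=bin_size,
        contig_lengths=contig_lengths,
        normalized=bool(int(meta.get("normalized", "0"))),
        total_reads=int(meta.get("total_reads", "0")),
    )
    filled: dict[str, np.ndarray] = {
        c: np.zeros(len(track.data[c]), dtype=bool) for c in track.data
    }
    for contig, start, end, value in rows:
        if contig not in track.data:
            raise ValueError(f"unknown contig {contig!r} in bedGraph")
        if start % bin_size:
            raise ValueError(f"interval start {start} not on the {bin_size} bp grid")
        b0 = start // bin_size
        b1 = math.ceil(end / bin_size)
        if filled[contig][b0:b1].any():
            raise ValueError(f"overlapping bedGraph intervals at {contig}:{start}")
        filled[contig][b0:b1] = True
        track.data[contig][b0:b1] = value
    return track
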