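"""Minimal genome description shared across modules."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of named contigs with lengths in bp.

    A desk-scale stand-in for a reference assembly: the default toy genome
    used throughout is a single 10 Mb contig.
    """

    contigs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for name, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)

    def length_of(self, contig: str) -> int:
        for name, length in self.contigs:
            if name == contig:
                return length
        raise KeyError(contig)


def toy_genome(length: int = 10_000_000, name: str = "chrS") -> GenomeSpec:
    """One-contig genome used by the synthetic experiments."""
    return GenomeSpec(contigs=((name, length),))


def read_genome_tsv(path) -> GenomeSpec:
    """Two-column TSV (contig name, length in bp) -> GenomeSpec."""
    contigs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            contigs.append((name, int(length)))
    return GenomeSpec(contigs=tuple(contigs))


def write_genome_tsv(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.contigs:
            fh.write(f"{name}\t{length}\n")
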