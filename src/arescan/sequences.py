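"""In-memory genome store: FASTA I/O, slicing, reverse complementation.

Coordinates are 0-based half-open throughout.  Genomes at the scales handled
here (synthetic chromosomes up to tens of Mb) are held fully in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (N maps to N)."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot complement character(s): {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Mapping of chromosome name to uppercase nucleotide string."""

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.sequences == other.sequences


def read_fasta(path) -> Genome:
    """Read a (multi-record, possibly line-wrapped) FASTA into a Genome.

    Header lines are truncated at the first whitespace to form chromosome
    names; sequence is uppercased.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise ValueError(f"duplicate chromosome name in FASTA: {name}")
        sequences[name] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences=sequences)


def write_fasta(genome: Genome, path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def extract(genome: Genome, chrom: str, start: int, end: int) -> str:
    """Half-open slice [start, end) of one chromosome; no silent clamping."""
    if chrom not in genome.sequences:
        raise KeyError(f"unknown chromosome {chrom!r}")
    size = len(genome.sequences[chrom])
    if not (0 <= start < end <= size):
        raise ValueError(
            f"coordinates [{start}, {end}) out of range for {chrom} (size {size})"
        )
    return genome.sequences[chrom][start:end]


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            name, size = fields[0], int(fields[1])
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name}")
            sizes[name] = size
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")
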