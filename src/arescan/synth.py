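"""Seeded synthetic scenarios: genomes with planted motifs plus truth manifest.

Everything stochastic draws from one explicitly passed numpy Generator, so a
fixed seed reproduces the emitted file set byte for byte.  Expected scores in
the manifest come from :func:`oracle_relative_score`, a deliberately plain
re-derivation of the scoring formula that shares no code with the scanner
under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .intervals import GenomicInterval, TranscriptRecord, write_bed
from .motif import PFM, load_bundled_pfm
from .sequences import (
    Genome,
    extract,
    reverse_complement,
    write_chrom_sizes,
    write_fasta,
)

BASES = "ACGT"


def oracle_relative_score(
    pfm: PFM, window: str, pseudocount: float = 1.0, background: Optional[list[float]] = None
) -> float:
    """Relative score recomputed from raw counts with plain Python.

    Independent of the numpy scoring path: per-column pseudo-counted
    frequencies, log2 odds against the background, summed; then rescaled
    between the per-column minima/maxima sums.
    """
    bg = background or [0.25, 0.25, 0.25, 0.25]
    width = pfm.width
    if len(window) != width:
        raise ValueError("window width mismatch")
    col_scores: list[dict[str, float]] = []
    for j in range(width):
        total = sum(int(pfm.counts[i][j]) for i in range(4)) + 4 * pseudocount
        col = {}
        for i, base in enumerate(BASES):
            freq = (int(pfm.counts[i][j]) + pseudocount) / total
            col[base] = math.log2(freq / bg[i])
        col_scores.append(col)
    absolute = sum(col_scores[j][window[j]] for j in range(width))
    max_score = sum(max(col.values()) for col in col_scores)
    min_score = sum(min(col.values()) for col in col_scores)
    return (absolute + abs(min_score)) / (abs(max_score) + abs(min_score))


def oracle_consensus(pfm: PFM) -> str:
    """Highest-count base per column (ties broken A<C<G<T)."""
    out = []
    for j in range(pfm.width):
        counts = [int(pfm.counts[i][j]) for i in range(4)]
        out.append(BASES[counts.index(max(counts))])
    return "".join(out)


def generate_genome(
    seed_or_rng, sizes: dict[str, int], base_probs: Optional[list[float]] = None
) -> Genome:
    """Random genome with bases drawn i.i.d. from ``base_probs``."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    probs = base_probs or [0.25, 0.25, 0.25, 0.25]
    sequences = {}
    for chrom, size in sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome size must be positive: {chrom}={size}")
        draws = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=size, p=probs)
        sequences[chrom] = draws.tobytes().decode("ascii")
    return Genome(sequences=sequences)


def plant_motif(genome: Genome, chrom: str, pos: int, sequence: str, strand: str = "+") -> Genome:
    """Overwrite the forward strand at ``pos`` with ``sequence``.

    Minus strand plants the reverse complement, so the motif reads as
    ``sequence`` on the minus strand.
    """
    if chrom not in genome.sequences:
        raise KeyError(f"unknown chromosome {chrom!r}")
    size = len(genome.sequences[chrom])
    if pos < 0 or pos + len(sequence) > size:
        raise ValueError(f"plant [{pos}, {pos + len(sequence)}) out of range (size {size})")
    if strand not in "+-":
        raise ValueError("strand must be + or -")
    forward = sequence.upper() if strand == "+" else reverse_complement(sequence)
    s = genome.sequences[chrom]
    genome.sequences[chrom] = s[:pos] + forward + s[pos + len(forward):]
    return genome


@dataclass(frozen=True)
class Plant:
    chrom: str
    position: int
    sequence: str  # as read on `strand`
    strand: str
    expected_relative_score: float
    in_peak: bool
    in_region: bool


@dataclass
class ScenarioSpec:
    """Counts and geometry for one synthetic scenario."""

    n_in_peak: int = 3  # above-threshold plants covered by peaks, in region
    n_off_peak: int = 0  # above-threshold plants in region but in no peak
    n_below_threshold: int = 0  # low-score plants covered by peaks
    chrom: str = "chrS"
    chrom_size: int = 60_000
    peak_halfwidth: int = 60
    flank: int = 5000
    tx_length: int = 8000
    threshold: float = 0.8
    tf_names: tuple[str, ...] = ("NFE2L2", "MAFK")
    segmentation_states: tuple[str, ...] = ("TSS", "T", "E")
    low_score_motif: Optional[str] = None  # default: per-column argmin W-mer


@dataclass
class ScenarioManifest:
    seed: int
    sizes: dict[str, int]
    plants: list[Plant]
    files: dict[str, str]
    threshold: float

    def expected_rows(self) -> list[Plant]:
        """Plants the pipeline must report: in a peak, in region, above threshold."""
        return [
            p
            for p in self.plants
            if p.in_peak and p.in_region and p.expected_relative_score >= self.threshold
        ]


def generate_scenario(
    seed: int,
    spec: ScenarioSpec,
    out_dir,
    pfm: Optional[PFM] = None,
) -> ScenarioManifest:
    """Emit FASTA, chrom.sizes, per-TF peak BEDs, transcripts, segmentation
    and a truth manifest for one scenario.

    Plants are separated by at least the motif width so truth accounting is
    unambiguous.  Off-peak plants are placed clear of every peak footprint.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    pfm = pfm if pfm is not None else load_bundled_pfm()
    width = pfm.width
    consensus = oracle_consensus(pfm)
    low_motif = spec.low_score_motif or _argmin_motif(pfm)

    chrom, size = spec.chrom, spec.chrom_size
    genome = generate_genome(rng, {chrom: size})

    # one plus-strand transcript occupying the right part of the chromosome;
    # its 5-kb upstream extension is the planting arena
    tx_start = spec.flank + 1000
    tx_end = min(size, tx_start + spec.tx_length)
    tx = TranscriptRecord(
        accession="NM_000001", chrom=chrom, strand="+", tx_start=tx_start, tx_end=tx_end
    )
    region_start, region_end = tx_start - spec.flank, tx_end

    margin = spec.peak_halfwidth + width
    n_total = spec.n_in_peak + spec.n_off_peak + spec.n_below_threshold
    positions = _place(rng, region_start + margin, region_end - margin, n_total, 2 * margin + width)

    plants: list[Plant] = []
    peak_rows: list[GenomicInterval] = []
    idx = 0
    for kind, count in (
        ("in_peak", spec.n_in_peak),
        ("off_peak", spec.n_off_peak),
        ("below", spec.n_below_threshold),
    ):
        for _ in range(count):
            pos = positions[idx]
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            seq = consensus if kind != "below" else low_motif
            plant_motif(genome, chrom, pos, seq, strand)
            in_peak = kind != "off_peak"
            if in_peak:
                tf = spec.tf_names[int(rng.integers(len(spec.tf_names)))]
                peak_rows.append(
                    GenomicInterval(
                        chrom,
                        max(0, pos - spec.peak_halfwidth),
                        min(size, pos + width + spec.peak_halfwidth),
                        label=tf,
                    )
                )
            plants.append(
                Plant(
                    chrom=chrom,
                    position=pos,
                    sequence=seq,
                    strand=strand,
                    expected_relative_score=oracle_relative_score(pfm, seq),
                    in_peak=in_peak,
                    in_region=True,
                )
            )

    # segmentation: tile the extended region with the given states
    seg_rows: list[GenomicInterval] = []
    if spec.segmentation_states:
        seg_len = max(200, (region_end - region_start) // (3 * len(spec.segmentation_states)))
        pos = region_start
        state_i = 0
        while pos + seg_len <= region_end:
            state = spec.segmentation_states[state_i % len(spec.segmentation_states)]
            seg_rows.append(GenomicInterval(chrom, pos, pos + seg_len, name=state))
            pos += seg_len
            state_i += 1

    files = {
        "fasta": str(out / "genome.fa"),
        "chrom_sizes": str(out / "genome.chrom.sizes"),
        "transcripts": str(out / "transcripts.bed"),
        "segmentation": str(out / "segmentation.bed"),
    }
    write_fasta(genome, files["fasta"])
    write_chrom_sizes(genome.sizes, files["chrom_sizes"])
    with open(files["transcripts"], "w") as fh:
        fh.write(f"{tx.chrom}\t{tx.tx_start}\t{tx.tx_end}\t{tx.accession}\t0\t{tx.strand}\n")
    write_bed(seg_rows, files["segmentation"])

    for tf in spec.tf_names:
        path = out / f"peaks_{tf}.bed"
        rows = [p for p in peak_rows if p.label == tf]
        write_bed(rows, path)
        files[f"peaks_{tf}"] = str(path)

    manifest = ScenarioManifest(
        seed=seed,
        sizes=dict(genome.sizes),
        plants=plants,
        files=files,
        threshold=spec.threshold,
    )
    _write_manifest(manifest, out / "manifest.yaml")
    manifest.files["manifest"] = str(out / "manifest.yaml")
    return manifest


def _argmin_motif(pfm: PFM) -> str:
    """Per-column lowest-count W-mer (relative score 0 under any background)."""
    out = []
    for j in range(pfm.width):
        counts = [int(pfm.counts[i][j]) for i in range(4)]
        out.append(BASES[counts.index(min(counts))])
    return "".join(out)


def _place(rng: np.random.Generator, lo: int, hi: int, n: int, min_sep: int, max_tries: int = 1000) -> list[int]:
    """n positions in [lo, hi) pairwise separated by >= min_sep."""
    if n == 0:
        return []
    for _ in range(max_tries):
        candidate = sorted(int(x) for x in rng.integers(lo, hi, size=n))
        if all(b - a >= min_sep for a, b in zip(candidate, candidate[1:])):
            return candidate
    raise RuntimeError(
        f"could not place {n} positions with separation {min_sep} in [{lo}, {hi})"
    )


def _write_manifest(manifest: ScenarioManifest, path) -> None:
    # paths are written relative to the manifest so identical seeds give
    # byte-identical file sets in any output directory
    doc = {
        "seed": manifest.seed,
        "threshold": manifest.threshold,
        "sizes": manifest.sizes,
        "files": {role: Path(p).name for role, p in manifest.files.items()},
        "plants": [
            {
                "chrom": p.chrom,
                "position": p.position,
                "sequence": p.sequence,
                "strand": p.strand,
                "expected_relative_score": p.expected_relative_score,
                "in_peak": p.in_peak,
                "in_region": p.in_region,
            }
            for p in manifest.plants
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_manifest(path) -> ScenarioManifest:
    base = Path(path).parent
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ScenarioManifest(
        seed=doc["seed"],
        sizes=doc["sizes"],
        plants=[Plant(**p) for p in doc["plants"]],
        files={role: str(base / p) for role, p in doc["files"].items()},
        threshold=doc["threshold"],
    )
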