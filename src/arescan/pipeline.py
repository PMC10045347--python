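"""End-to-end ARE discovery: extended transcripts x ChIP peaks -> scored sites.

Stages: extend each transcript 5000 bp upstream of its TSS, intersect the
extended regions with every labelled peak set, extract the peak sequences,
scan them on both strands with the relative-score threshold, map hits back
to genomic coordinates, merge duplicate hits found through multiple peaks
(unioning their TF labels), annotate regulatory-segmentation states, and
emit one report row per (gene, site, strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import motif as mm
from .intervals import (
    GenomicInterval,
    TranscriptRecord,
    annotate_segmentation,
    extend_upstream,
    intersect,
    read_bed,
    read_transcript_table,
)
from .sequences import Genome, extract, read_chrom_sizes, read_fasta

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "Gene",
    "Coordinates",
    "Motif",
    "RelativeScore",
    "Strand",
    "RegulatoryElement",
    "TFs",
]


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero (table convention), not banker's."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_coordinates(chrom: str, start: int, end: int) -> str:
    """Render "chrom:start-end" (no thousands separators)."""
    if start >= end:
        raise ValueError(f"start {start} >= end {end}")
    return f"{chrom}:{start}-{end}"


def parse_coordinates(text: str) -> tuple[str, int, int]:
    chrom, _, span = text.rpartition(":")
    start_s, _, end_s = span.partition("-")
    return chrom, int(start_s), int(end_s)


@dataclass(frozen=True)
class AREReportRow:
    """One line of the output table."""

    gene: str
    coordinates: str
    motif: str
    relative_score: float  # full precision; rounded only on rendering
    strand: str
    regulatory_elements: tuple[str, ...]
    tfs: tuple[str, ...]
    transcript_strand: Optional[str] = None

    @property
    def transcript_relative_strand(self) -> Optional[str]:
        """Strand of the match relative to the owning transcript's sense."""
        if self.transcript_strand is None:
            return None
        return "+" if self.strand == self.transcript_strand else "-"

    def render(self, decimals: int = 3) -> list[str]:
        return [
            self.gene,
            self.coordinates,
            self.motif,
            f"{round_half_up(self.relative_score, decimals):.{decimals}f}",
            self.strand,
            ", ".join(self.regulatory_elements) or "None",
            ", ".join(self.tfs),
        ]


@dataclass
class PipelineConfig:
    pfm: str
    genome_fasta: str
    chrom_sizes: str
    transcripts: str
    peaks: list[tuple[str, str]]  # (TF name, BED path)
    segmentation: Optional[str] = None
    gene_map: dict[str, str] = field(default_factory=dict)  # accession -> gene
    background: Optional[Sequence[float]] = None  # None = uniform
    pseudocount: float = 1.0
    flank: int = 5000
    threshold: float = 0.8
    score_decimals: int = 3
    output: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


def load_config(path) -> PipelineConfig:
    """Read a YAML config mirroring PipelineConfig (paths relative to it)."""
    base = Path(path).parent
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def _p(value: str) -> str:
        p = Path(value)
        return str(p if p.is_absolute() else base / p)

    peaks = [(item["tf"], _p(item["bed"])) for item in raw["peaks"]]
    return PipelineConfig(
        pfm=_p(raw["pfm"]),
        genome_fasta=_p(raw["genome_fasta"]),
        chrom_sizes=_p(raw["chrom_sizes"]),
        transcripts=_p(raw["transcripts"]),
        peaks=peaks,
        segmentation=_p(raw["segmentation"]) if raw.get("segmentation") else None,
        gene_map=dict(raw.get("gene_map", {})),
        background=raw.get("background"),
        pseudocount=float(raw.get("pseudocount", 1.0)),
        flank=int(raw.get("flank", 5000)),
        threshold=float(raw.get("threshold", 0.8)),
        score_decimals=int(raw.get("score_decimals", 3)),
        output=_p(raw["output"]) if raw.get("output") else None,
    )


@dataclass(frozen=True)
class _LocatedHit:
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    absolute_score: float
    relative_score: float
    gene: str
    transcript_strand: str
    tf: str


def merge_tf_labels(hits: Sequence[_LocatedHit]) -> list[tuple[_LocatedHit, tuple[str, ...]]]:
    """Collapse hits identical on (gene, chrom, start, end, strand).

    The same site reached through peaks of several factors becomes one
    record carrying the sorted unique union of TF labels.
    """
    merged: dict[tuple, tuple[_LocatedHit, set[str]]] = {}
    for h in hits:
        key = (h.gene, h.chrom, h.start, h.end, h.strand)
        if key in merged:
            merged[key][1].add(h.tf)
        else:
            merged[key] = (h, {h.tf})
    return [(h, tuple(sorted(tfs))) for h, tfs in merged.values()]


def _check_files(config: PipelineConfig) -> None:
    needed = {
        "pfm": config.pfm,
        "genome_fasta": config.genome_fasta,
        "chrom_sizes": config.chrom_sizes,
        "transcripts": config.transcripts,
    }
    if config.segmentation:
        needed["segmentation"] = config.segmentation
    for tf, bed in config.peaks:
        needed[f"peaks[{tf}]"] = bed
    missing = [f"{role}: {path}" for role, path in needed.items() if not Path(path).exists()]
    if missing:
        raise FileNotFoundError("missing input file(s): " + "; ".join(missing))


def run_pipeline(
    config: PipelineConfig,
    genome: Optional[Genome] = None,
    stats: Optional[mm.ScanStats] = None,
) -> list[AREReportRow]:
    """Run the full analysis; returns rows sorted by (gene, chrom, start, strand)."""
    _check_files(config)
    pfm = mm.load_pfm(config.pfm)
    pssm = mm.build_pssm(pfm, background=config.background, pseudocount=config.pseudocount)
    if genome is None:
        genome = read_fasta(config.genome_fasta)
    sizes = read_chrom_sizes(config.chrom_sizes)

    transcripts = read_transcript_table(config.transcripts)
    if config.gene_map:
        transcripts = [t for t in transcripts if t.accession in config.gene_map]
    if not transcripts:
        raise ValueError("no transcripts remain after gene-map filtering")
    gene_of = {
        t.accession: config.gene_map.get(t.accession, t.accession) for t in transcripts
    }
    regions = [extend_upstream(t, config.flank, sizes) for t in transcripts]
    tx_strand = {t.accession: t.strand for t in transcripts}

    peaks: list[GenomicInterval] = []
    for tf, bed_path in config.peaks:
        peaks.extend(read_bed(bed_path, label=tf))

    scan_stats = stats if stats is not None else mm.ScanStats()
    located: list[_LocatedHit] = []
    scanned_peaks: dict[tuple, list[mm.MotifHit]] = {}
    for region, peak, _overlap in intersect(regions, peaks):
        peak_key = (peak.chrom, peak.start, peak.end)
        if peak_key not in scanned_peaks:
            seq = extract(genome, peak.chrom, peak.start, peak.end)
            scanned_peaks[peak_key] = mm.scan_sequence(
                pssm,
                seq,
                threshold=config.threshold,
                both_strands=True,
                chrom=peak.chrom,
                offset=peak.start,
                stats=scan_stats,
            )
        for hit in scanned_peaks[peak_key]:
            # hit must lie wholly inside the peak (guaranteed by scanning the
            # peak sequence) and overlap the extended transcript region
            if hit.start < region.end and region.start < hit.end:
                located.append(
                    _LocatedHit(
                        chrom=hit.chrom,
                        start=hit.start,
                        end=hit.end,
                        strand=hit.strand,
                        sequence=hit.sequence,
                        absolute_score=hit.absolute_score,
                        relative_score=hit.relative_score,
                        gene=gene_of[region.name],
                        transcript_strand=tx_strand[region.name],
                        tf=peak.label or "",
                    )
                )

    segmentation = read_bed(config.segmentation) if config.segmentation else []
    # segmentation BEDs carry the state in the name column
    segmentation = [
        GenomicInterval(s.chrom, s.start, s.end, name=s.name, strand=s.strand, label=s.name)
        for s in segmentation
    ]

    rows = []
    for hit, tfs in merge_tf_labels(located):
        site = GenomicInterval(hit.chrom, hit.start, hit.end)
        labels = annotate_segmentation(site, segmentation)
        rows.append(
            AREReportRow(
                gene=hit.gene,
                coordinates=format_coordinates(hit.chrom, hit.start, hit.end),
                motif=hit.sequence,
                relative_score=hit.relative_score,
                strand=hit.strand,
                regulatory_elements=tuple(labels),
                tfs=tfs,
                transcript_strand=hit.transcript_strand,
            )
        )
    rows.sort(key=lambda r: (r.gene, parse_coordinates(r.coordinates), r.strand))
    logger.info(
        "scan: %d windows scanned, %d skipped (non-ACGT), %d hits, %d rows",
        scan_stats.windows_scanned,
        scan_stats.windows_skipped,
        scan_stats.hits_above_threshold,
        len(rows),
    )
    return rows


def write_report(rows: Sequence[AREReportRow], path, decimals: int = 3) -> None:
    """TSV report shaped like the published site tables."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row.render(decimals)) + "\n")


def write_sites_bed(rows: Sequence[AREReportRow], path) -> None:
    """BED6 export; score column is relative score x 1000 (BED convention)."""
    with open(path, "w") as fh:
        for row in rows:
            chrom, start, end = parse_coordinates(row.coordinates)
            score = int(
                Decimal(repr(row.relative_score))
                .scaleb(3)
                .quantize(Decimal(1), rounding=ROUND_HALF_UP)
            )
            fh.write(f"{chrom}\t{start}\t{end}\t{row.gene}\t{score}\t{row.strand}\n")
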