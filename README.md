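# arescan

Discovery of putative antioxidant response elements (AREs) in ChIP-peak-
supported promoter regions.  The pipeline:

1. reads transcript coordinates and extends each transcript 5000 bp upstream
   of its transcription start site (strand-aware, clamped to the chromosome);
2. intersects the extended regions with labelled ChIP-seq peak BED files
   (one transcription factor per file);
3. extracts the peak sequences from a genome FASTA and slides the NFE2L2
   binding profile (JASPAR MA0150.1, vendored) over both strands;
4. scores each window with a pseudo-counted log2-odds PSSM, converts the
   absolute score to a relative score
   `(absolute + |minScore|) / (|maxScore| + |minScore|)`, and discards
   windows below 0.8;
5. merges identical sites found through peaks of several factors (unioning
   their TF labels), annotates regulatory-segmentation states, and emits a
   TSV report (Gene / Coordinates / Motif / RelativeScore / Strand /
   RegulatoryElement / TFs) plus an optional BED6 export.

A seeded synthetic-data module generates genomes with planted motifs,
peaks, transcripts, segmentations and a truth manifest, so the whole
pipeline is testable without any downloads.

## CLI

```sh
# inspect the scoring matrix built from a JASPAR PFM
arescan build-pssm --pfm src/arescan/data/MA0150.1.jaspar

# scan a FASTA on both strands at the 0.8 relative-score threshold
arescan scan --pfm src/arescan/data/MA0150.1.jaspar --fasta genome.fa --threshold 0.8

# generate a synthetic scenario with a truth manifest
arescan synth --seed 7 --out scenario/

# run the full analysis from a YAML config
arescan pipeline --config config.yaml --out report.tsv --bed sites.bed
```

A pipeline config lists the input files and parameters (paths are resolved
relative to the config file):

```yaml
pfm: MA0150.1.jaspar
genome_fasta: genome.fa
chrom_sizes: genome.chrom.sizes
transcripts: transcripts.bed        # BED6 or UCSC Table-Browser TSV
segmentation: segmentation.bed      # optional; state in the name column
peaks:
  - {tf: NFE2L2, bed: peaks_NFE2L2.bed}
  - {tf: MAFK, bed: peaks_MAFK.bed}
gene_map: {NM_000001: DNMT1}        # optional accession -> gene filter
flank: 5000
threshold: 0.8
pseudocount: 1
```

## Layout

- `src/arescan/motif.py` — PFM parsing, PSSM construction, window scoring,
  bidirectional threshold scanning
- `src/arescan/sequences.py` — FASTA/chrom.sizes I/O, slicing, reverse
  complement
- `src/arescan/intervals.py` — BED I/O, upstream extension, intersection,
  segmentation annotation
- `src/arescan/pipeline.py` — orchestration, TF-label merging, report I/O
- `src/arescan/synth.py` — seeded scenario generator + independent scoring
  oracle
- `tests/` — unit, property (hypothesis) and acceptance tests
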