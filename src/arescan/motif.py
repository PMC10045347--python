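"""Position frequency matrices, log2-odds PSSMs, and relative-score scanning.

A PFM holds raw base counts per motif position (JASPAR flat-file layout).
It is converted to a PSSM of log2(observed/expected) scores after adding a
pseudocount to every count, and sequences are scanned with a sliding window:
the per-position scores of a window are summed into an absolute score, which
is mapped onto [0, 1] as

    relative = (absolute + |min_score|) / (|max_score| + |min_score|)

where ``max_score``/``min_score`` are the best and worst absolute scores any
window can attain.  Windows below a relative-score threshold are discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

import numpy as np

from .sequences import reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: id of the bundled NFE2L2 binding profile
BUNDLED_PFM_ID = "MA0150.1"


class MotifFormatError(ValueError):
    """Raised when a matrix record cannot be parsed."""


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: integer counts, rows A/C/G/T."""

    motif_id: str
    counts: np.ndarray  # shape (4, width), int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise MotifFormatError(
                f"counts must be a 4 x W matrix, got shape {counts.shape}"
            )
        if counts.shape[1] < 1:
            raise MotifFormatError("motif width must be >= 1")
        if (counts < 0).any():
            raise MotifFormatError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PFM):
            return NotImplemented
        return self.motif_id == other.motif_id and np.array_equal(
            self.counts, other.counts
        )


@dataclass(frozen=True)
class PSSM:
    """Log2-odds scoring matrix with cached score extrema."""

    scores: np.ndarray  # shape (4, width), float
    max_score: float
    min_score: float
    background: np.ndarray  # shape (4,), float
    pseudocount: float
    motif_id: str = ""

    @property
    def width(self) -> int:
        return int(self.scores.shape[1])

    def consensus(self) -> str:
        """W-mer picking the top-scoring base at every position."""
        return "".join(BASES[i] for i in self.scores.argmax(axis=0))

    def anticonsensus(self) -> str:
        """W-mer picking the worst-scoring base at every position."""
        return "".join(BASES[i] for i in self.scores.argmin(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """A scored window located on a sequence (0-based half-open coords).

    ``start``/``end`` are always forward-strand coordinates; for a minus-
    strand hit ``sequence`` is the reverse complement of the forward-strand
    slice, i.e. the W-mer as matched by the motif.
    """

    chrom: str
    start: int
    end: int
    sequence: str
    absolute_score: float
    relative_score: float
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError("hit span does not match sequence length")


@dataclass
class ScanStats:
    """Counters accumulated while scanning (run-log material)."""

    windows_scanned: int = 0
    windows_skipped: int = 0  # contained non-ACGT characters
    hits_above_threshold: int = 0

    def merge(self, other: "ScanStats") -> None:
        self.windows_scanned += other.windows_scanned
        self.windows_skipped += other.windows_skipped
        self.hits_above_threshold += other.hits_above_threshold


# ---------------------------------------------------------------------------
# JASPAR parsing


def parse_jaspar_pfm(text: str) -> PFM:
    """Parse one JASPAR flat-format matrix record.

    Accepts both dialects: bare count rows in A/C/G/T order, and rows of the
    form ``A  [ 10  0 ... ]``.  The header line (``>MA0150.1 NFE2L2``) is
    optional for the bare dialect but used for the motif id when present.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MotifFormatError("empty matrix record")

    motif_id = ""
    if lines[0].startswith(">"):
        header = lines[0][1:].strip()
        motif_id = header.split()[0] if header else ""
        lines = lines[1:]

    rows: dict[str, list[int]] = {}
    order: list[str] = []
    for ln in lines:
        m = re.match(r"^([ACGTacgt])\s*[:\[]?\s*(.*?)\s*\]?\s*$", ln)
        if m and m.group(1).upper() in BASES and not rows.get(m.group(1).upper()):
            base = m.group(1).upper()
            body = m.group(2)
        elif len(order) < 4:
            base = BASES[len(order)]  # bare dialect: implicit A,C,G,T order
            body = ln.rstrip("]").lstrip("[")
        else:
            raise MotifFormatError(f"unexpected extra line in matrix record: {ln!r}")
        values = []
        for tok in body.split():
            try:
                v = float(tok)
            except ValueError:
                raise MotifFormatError(f"non-numeric count {tok!r} in row {base}")
            if v < 0:
                raise MotifFormatError(f"negative count {tok} in row {base}")
            if v != int(v):
                raise MotifFormatError(f"non-integer count {tok} in row {base}")
            values.append(int(v))
        if base in rows:
            raise MotifFormatError(f"duplicate row for base {base}")
        rows[base] = values
        order.append(base)

    missing = [b for b in BASES if b not in rows]
    if missing:
        raise MotifFormatError(f"missing base row(s): {', '.join(missing)}")
    widths = {b: len(v) for b, v in rows.items()}
    if len(set(widths.values())) != 1:
        raise MotifFormatError(f"unequal row lengths: {widths}")
    if widths["A"] == 0:
        raise MotifFormatError("matrix rows are empty")
    counts = np.array([rows[b] for b in BASES], dtype=int)
    return PFM(motif_id=motif_id, counts=counts)


def load_pfm(path) -> PFM:
    """Read a JASPAR PFM record from a file path."""
    with open(path) as fh:
        return parse_jaspar_pfm(fh.read())


def load_bundled_pfm(motif_id: str = BUNDLED_PFM_ID) -> PFM:
    """Load a matrix shipped with the package (default: NFE2L2, MA0150.1)."""
    ref = resources.files("arescan.data").joinpath(f"{motif_id}.jaspar")
    return parse_jaspar_pfm(ref.read_text())


# ---------------------------------------------------------------------------
# PSSM construction and scoring

UNIFORM_BACKGROUND = np.full(4, 0.25)


def build_pssm(
    pfm: PFM,
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> PSSM:
    """Turn counts into log2(observed/expected) scores.

    Each count gets ``pseudocount`` added, every column is normalised by its
    own (count sum + 4 * pseudocount), and the per-base background gives the
    expected frequency.  ``max_score``/``min_score`` are the sums of the
    per-column maxima/minima.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,):
        raise ValueError("background must have one probability per base (A,C,G,T)")
    if (bg <= 0).any():
        raise ValueError("background probabilities must be strictly positive")
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError(f"background must sum to 1, got {bg.sum()}")
    if pseudocount == 0 and (pfm.counts == 0).any():
        raise ValueError(
            "pseudocount 0 with a zero count would produce log(0); "
            "use a positive pseudocount"
        )
    adjusted = pfm.counts + pseudocount
    col_totals = pfm.counts.sum(axis=0) + 4.0 * pseudocount
    freqs = adjusted / col_totals
    scores = np.log2(freqs / bg[:, None])
    return PSSM(
        scores=scores,
        max_score=float(scores.max(axis=0).sum()),
        min_score=float(scores.min(axis=0).sum()),
        background=bg,
        pseudocount=float(pseudocount),
        motif_id=pfm.motif_id,
    )


def encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; any other character (N, IUPAC, ...) to -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def score_window(pssm: PSSM, window: str) -> float:
    """Sum the per-position scores of one W-mer."""
    if len(window) != pssm.width:
        raise ValueError(
            f"window length {len(window)} != motif width {pssm.width}"
        )
    codes = encode(window)
    if (codes < 0).any():
        bad = window[int(np.argmax(codes < 0))]
        raise ValueError(f"window contains non-ACGT character {bad!r}")
    return float(pssm.scores[codes, np.arange(pssm.width)].sum())


def relative_score(pssm: PSSM, absolute: float) -> float:
    """Map an absolute score onto [0, 1] between the matrix extrema."""
    denom = abs(pssm.max_score) + abs(pssm.min_score)
    if denom == 0:
        raise ValueError(
            "degenerate matrix: every window scores identically, "
            "relative score is undefined"
        )
    tol = 1e-9 * max(1.0, abs(pssm.max_score), abs(pssm.min_score))
    if absolute < pssm.min_score - tol or absolute > pssm.max_score + tol:
        raise ValueError(
            f"absolute score {absolute} outside "
            f"[{pssm.min_score}, {pssm.max_score}]"
        )
    return (absolute + abs(pssm.min_score)) / (
        abs(pssm.max_score) + abs(pssm.min_score)
    )


def _strand_scores(pssm: PSSM, codes: np.ndarray, matrix: np.ndarray):
    """Vectorised window sums; returns (scores, valid) per offset."""
    w = pssm.width
    n = len(codes) - w + 1
    totals = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    safe = codes.copy()
    safe[safe < 0] = 0
    for j in range(w):
        col = codes[j : j + n]
        valid &= col >= 0
        totals += matrix[safe[j : j + n], j]
    return totals, valid

def scan_sequence(
    pssm: PSSM,
    seq: str,
    threshold: float = 0.8,
    both_strands: bool = True,
    chrom: str = "",
    offset: int = 0,
    stats: ScanStats | None = None,
) -> list[MotifHit]:
    """Slide the motif over ``seq`` and keep windows at/above ``threshold``.

    Every offset is scored on the forward strand and, with ``both_strands``,
    on the reverse complement of the same window; minus-strand hits keep the
    forward coordinates and report the reverse-complemented W-mer.  Windows
    containing non-ACGT characters are skipped (counted in ``stats``).
    Coordinates are relative to the sequence origin plus ``offset``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    w = pssm.width
    if len(seq) < w:
        return []
    seq = seq.upper()
    codes = encode(seq)
    denom = abs(pssm.max_score) + abs(pssm.min_score)
    if denom == 0:
        raise ValueError("degenerate matrix: relative score is undefined")
    lo = abs(pssm.min_score)

    strands: list[tuple[str, np.ndarray]] = [("+", pssm.scores)]
    if both_strands:
        # scoring revcomp(window) with M == scoring window with M reversed
        # along positions and complemented along bases (A<->T, C<->G)
        rc_matrix = pssm.scores[::-1, ::-1]
        strands.append(("-", rc_matrix))

    hits: list[MotifHit] = []
    local = ScanStats()
    for strand, matrix in strands:
        totals, valid = _strand_scores(pssm, codes, matrix)
        local.windows_scanned += int(valid.sum())
        local.windows_skipped += int((~valid).sum())
        rel = np.where(valid, (totals + lo) / denom, -1.0)
        # vectorised sums can drift by an ulp; candidates near or above the
        # threshold are rescored with score_window so reported scores match
        # standalone rescoring bit for bit
        for i in np.flatnonzero(rel >= threshold - 1e-9):
            window = seq[i : i + w]
            mer = window if strand == "+" else reverse_complement(window)
            absolute = score_window(pssm, mer)
            relative = relative_score(pssm, absolute)
            if relative < threshold:
                continue
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=offset + int(i),
                    end=offset + int(i) + w,
                    sequence=mer,
                    absolute_score=absolute,
                    relative_score=relative,
                    strand=strand,
                )
            )
    local.hits_above_threshold = len(hits)
    if stats is not None:
        stats.merge(local)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
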