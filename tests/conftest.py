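"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-enumerate windows/pairs with plain loops so
they share no control flow with the vectorised implementations they check.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from arescan.motif import PFM, PSSM, build_pssm, load_bundled_pfm, parse_jaspar_pfm
from arescan.motif import relative_score, score_window
from arescan.pipeline import PipelineConfig
from arescan.sequences import reverse_complement

TOY_PFM_TEXT = """\
>TOY1 toy
A [ 3 0 ]
C [ 0 3 ]
G [ 0 0 ]
T [ 0 0 ]
"""


@pytest.fixture(scope="session")
def ma0150() -> PFM:
    return load_bundled_pfm()


@pytest.fixture(scope="session")
def ma0150_pssm(ma0150) -> PSSM:
    return build_pssm(ma0150)


@pytest.fixture()
def toy_pfm() -> PFM:
    return parse_jaspar_pfm(TOY_PFM_TEXT)


@pytest.fixture()
def toy_pssm(toy_pfm) -> PSSM:
    return build_pssm(toy_pfm)


def brute_force_scan(
    pssm: PSSM, seq: str, threshold: float, both_strands: bool = True
) -> set[tuple[int, int, str, float]]:
    """Enumerate every offset and strand; rescore with score_window.

    Returns {(start, end, strand, round(relative, 12))} for comparison with
    the scanner's hit list.
    """
    seq = seq.upper()
    w = pssm.width
    found = set()
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if any(c not in "ACGT" for c in window):
            continue
        candidates = [("+", window)]
        if both_strands:
            candidates.append(("-", reverse_complement(window)))
        for strand, mer in candidates:
            rel = relative_score(pssm, score_window(pssm, mer))
            if rel >= threshold:
                found.add((i, i + w, strand, round(rel, 12)))
    return found


def hits_as_set(hits) -> set[tuple[int, int, str, float]]:
    return {(h.start, h.end, h.strand, round(h.relative_score, 12)) for h in hits}


def brute_force_intersect(a, b):
    """Quadratic all-pairs overlap oracle (half-open semantics)."""
    out = []
    for av in a:
        for bv in b:
            if av.chrom == bv.chrom and av.start < bv.end and bv.start < av.end:
                out.append((av, bv, max(av.start, bv.start), min(av.end, bv.end)))
    return out


def config_from_manifest(manifest, pfm_path: str, **overrides) -> PipelineConfig:
    """PipelineConfig pointing at one synthetic scenario's emitted files."""
    peaks = [
        (role[len("peaks_"):], path)
        for role, path in sorted(manifest.files.items())
        if role.startswith("peaks_")
    ]
    kwargs = dict(
        pfm=pfm_path,
        genome_fasta=manifest.files["fasta"],
        chrom_sizes=manifest.files["chrom_sizes"],
        transcripts=manifest.files["transcripts"],
        peaks=peaks,
        segmentation=manifest.files.get("segmentation"),
        threshold=manifest.threshold,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def pfm_path() -> str:
    from importlib import resources

    return str(resources.files("arescan.data").joinpath("MA0150.1.jaspar"))


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
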