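"""Motif-based family identification in a proteome.

Family members are called by Smith–Waterman local alignment of a conserved
44-residue consensus (the C-terminal PSPG box of plant UDP-
glycosyltransferases) against every protein, scoring with BLOSUM62 and
affine gaps (open 10, extend 1). A protein is called when its best local
alignment reaches a configurable fraction of the motif's self-alignment
score — a flat-consensus stand-in for a database similarity search, with no
E-value model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "MotifHit",
    "make_aligner",
    "local_align_motif",
    "scan_proteome",
    "read_proteome",
]

DEFAULT_SCORE_FRACTION = 0.40
_STANDARD = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; nonstandard residues are scored as X."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if "-" in self.sequence:
            raise ValueError(f"{self.id}: gap characters in unaligned sequence")


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    raw_score: float
    score_fraction: float
    span: tuple[int, int]  # 1-based inclusive on the protein
    motif_coverage: float


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str, seq_id: str) -> str:
    cleaned = seq.upper()
    bad = set(cleaned) - _STANDARD
    if bad:
        logger.warning("%s: residues %s scored as X", seq_id, sorted(bad))
        for ch in bad:
            cleaned = cleaned.replace(ch, "X")
    return cleaned


def local_align_motif(
    protein: ProteinRecord,
    motif: str,
    aligner: Align.PairwiseAligner | None = None,
) -> MotifHit:
    """Best local alignment of the motif to one protein.

    ``score_fraction`` is the alignment score over the motif's score against
    itself under the same scoring scheme, capped into [0, 1];
    ``motif_coverage`` the fraction of motif residues inside aligned blocks.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if aligner is None:
        aligner = make_aligner()
    motif = _sanitize(motif, "motif")
    seq = _sanitize(protein.sequence, protein.id)
    self_score = aligner.score(motif, motif)
    aln = next(iter(aligner.align(seq, motif)))
    target_blocks, query_blocks = aln.aligned
    start = int(target_blocks[0][0]) + 1
    end = int(target_blocks[-1][1])
    covered = sum(int(b - a) for a, b in query_blocks)
    return MotifHit(
        protein_id=protein.id,
        raw_score=float(aln.score),
        score_fraction=min(max(float(aln.score) / self_score, 0.0), 1.0),
        span=(start, end),
        motif_coverage=covered / len(motif),
    )


def scan_proteome(
    proteome: list[ProteinRecord],
    motif: str,
    threshold: float = DEFAULT_SCORE_FRACTION,
    aligner: Align.PairwiseAligner | None = None,
) -> list[MotifHit]:
    """Family call set: proteins whose best hit reaches ``threshold``.

    Results are sorted by descending score fraction, then id; the scan is
    deterministic and an empty proteome yields an empty result.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    seen: set[str] = set()
    for rec in proteome:
        if rec.id in seen:
            raise ValueError(f"duplicate protein id: {rec.id}")
        seen.add(rec.id)
    if aligner is None:
        aligner = make_aligner()
    hits = [local_align_motif(rec, motif, aligner) for rec in proteome]
    called = [h for h in hits if h.score_fraction >= threshold]
    called.sort(key=lambda h: (-h.score_fraction, h.protein_id))
    return called


def read_proteome(path) -> list[ProteinRecord]:
    return [
        ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
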