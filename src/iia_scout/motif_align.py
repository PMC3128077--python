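"""The conserved subunit-IIa motif scan and pairwise identity/similarity.

Subunit IIa sequences carry a short N-terminal motif — Pro, one to three
arbitrary residues, Gly, then Thr or Ala (P X{1,3} G [TA]) — and an
invariant Trp near the middle of the helix.  For candidate validation the
module also offers a global (Needleman-Wunsch) alignment under BLOSUM62 with
affine gaps, reporting percent identity and percent similarity, where
"similar" means the classic ClustalW strong conservation groups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

MOTIF_PATTERN = "PX(1-3)G[TA]"
_MOTIF_RE = re.compile(r"P.{1,3}?G[TA]")  # lazy quantifier: leftmost-shortest

# ClustalW strong conservation groups
STRONG_GROUPS = [
    frozenset("STA"), frozenset("NEQK"), frozenset("NHQK"), frozenset("NDEQ"),
    frozenset("QHRK"), frozenset("MILV"), frozenset("MILF"), frozenset("HY"),
    frozenset("FYW"),
]

__all__ = [
    "MotifHit",
    "AlignmentResult",
    "MOTIF_PATTERN",
    "STRONG_GROUPS",
    "scan_motif",
    "has_conserved_trp",
    "pairwise_identity_similarity",
]


@dataclass
class MotifHit:
    position: int  # 1-based residue index of the Pro
    matched_text: str
    pattern: str = MOTIF_PATTERN


def scan_motif(peptide: str) -> list[MotifHit]:
    """Non-overlapping, leftmost-shortest occurrences of P X{1,3} G [TA]."""
    return [
        MotifHit(position=m.start() + 1, matched_text=m.group())
        for m in _MOTIF_RE.finditer(peptide.upper())
    ]


def has_conserved_trp(peptide: str) -> bool:
    """Presence of the conserved tryptophan (any W in the sequence)."""
    return "W" in peptide.upper()


@dataclass
class AlignmentResult:
    identity_pct: float
    similarity_pct: float
    aligned_length: int
    gaps: int
    score: float
    aligned_a: str
    aligned_b: str


def _similar(x: str, y: str) -> bool:
    if x == y:
        return True
    return any(x in g and y in g for g in STRONG_GROUPS)


def pairwise_identity_similarity(
    a: str,
    b: str,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignmentResult:
    """Global BLOSUM62 alignment; percentages use the full alignment length
    (gap columns included) as denominator."""
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    a, b = a.upper(), b.upper()
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])

    length = len(ga)
    ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    simil = sum(
        1 for x, y in zip(ga, gb) if x != "-" and y != "-" and _similar(x, y)
    )
    gaps = ga.count("-") + gb.count("-")
    return AlignmentResult(
        identity_pct=100.0 * ident / length,
        similarity_pct=100.0 * simil / length,
        aligned_length=length,
        gaps=gaps,
        score=float(aln.score),
        aligned_a=ga,
        aligned_b=gb,
    )
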