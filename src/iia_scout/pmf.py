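"""In-silico tryptic digestion and peptide-mass-fingerprint coverage.

Trypsin cleaves C-terminal to Lys/Arg except when the next residue is Pro.
Observed PMF masses are matched as [M+H]+ monoisotopic ions; the union of
matched peptide intervals gives the sequence coverage, and an optional
N-terminal interval (e.g. a re-annotated extension of a protein) is checked
for overlap with any matched peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .mass_core import PROTON, peptide_mass, ppm_delta

__all__ = ["DigestPeptide", "CoverageResult", "tryptic_digest", "pmf_coverage"]


@dataclass
class DigestPeptide:
    start_aa: int  # 1-based inclusive in the parent
    end_aa: int
    sequence: str
    missed_cleavages: int
    mono_mass: float


@dataclass
class CoverageResult:
    covered_fraction: float  # % of parent residues inside >=1 matched peptide
    matched: list[DigestPeptide]
    covers_extension: bool


def _cleavage_boundaries(parent: str) -> list[int]:
    """0-based indices i such that trypsin cuts between parent[i-1] and
    parent[i]; includes 0 and len(parent)."""
    bounds = [0]
    for i in range(len(parent) - 1):
        if parent[i] in "KR" and parent[i + 1] != "P":
            bounds.append(i + 1)
    bounds.append(len(parent))
    return bounds


def tryptic_digest(parent: str, max_missed: int = 0) -> list[DigestPeptide]:
    """All tryptic peptides of ``parent`` with 0..max_missed missed cleavages,
    ordered by start position then length."""
    if not parent:
        raise ValueError("empty parent sequence")
    parent = parent.upper()
    bounds = _cleavage_boundaries(parent)
    peptides = []
    for bi in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            bj = bi + 1 + missed
            if bj >= len(bounds):
                break
            s, e = bounds[bi], bounds[bj]
            seq = parent[s:e]
            peptides.append(
                DigestPeptide(
                    start_aa=s + 1,
                    end_aa=e,
                    sequence=seq,
                    missed_cleavages=missed,
                    mono_mass=peptide_mass(seq, "monoisotopic"),
                )
            )
    peptides.sort(key=lambda p: (p.start_aa, p.end_aa))
    return peptides


def pmf_coverage(
    parent: str,
    observed_masses: Sequence[float],
    tolerance_ppm: float = 50.0,
    max_missed: int = 1,
    n_term_interval: Optional[tuple[int, int]] = None,
) -> CoverageResult:
    """Match observed [M+H]+ masses to the digest and report coverage.

    ``n_term_interval`` is a 1-based inclusive residue range (such as a newly
    annotated N-terminal extension); ``covers_extension`` is true when any
    matched peptide overlaps it.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    parent = parent.upper()
    digest = tryptic_digest(parent, max_missed=max_missed)
    matched: list[DigestPeptide] = []
    for pep in digest:
        theo = pep.mono_mass + PROTON
        if any(abs(ppm_delta(m, theo)) <= tolerance_ppm for m in observed_masses):
            matched.append(pep)

    covered = set()
    for pep in matched:
        covered.update(range(pep.start_aa, pep.end_aa + 1))
    fraction = 100.0 * len(covered) / len(parent)

    covers_ext = False
    if n_term_interval is not None:
        lo, hi = n_term_interval
        covers_ext = any(
            pep.start_aa <= hi and pep.end_aa >= lo for pep in matched
        )
    return CoverageResult(
        covered_fraction=fraction, matched=matched, covers_extension=covers_ext
    )
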