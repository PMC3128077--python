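"""Windowed Kyte-Doolittle hydropathy and the single-helix candidacy filter.

A membrane-spanning helix shows up as a run of high-hydropathy sliding
windows.  The caller here merges maximal runs of above-threshold windows into
segments; distinct runs stay distinct segments (two hydrophobic cores
separated by a hydrophilic linker are two helices), and where the union spans
of neighbouring runs overlap by a few residues the boundary is split at the
overlap midpoint so that segments never overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

# Kyte & Doolittle (1982) hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_SEGMENT = 15
CANDIDATE_LENGTH_RANGE = (25, 100)

__all__ = [
    "TMSegment",
    "KYTE_DOOLITTLE",
    "hydropathy_profile",
    "call_tm_segments",
    "is_candidate_iia",
]


@dataclass
class TMSegment:
    """A predicted membrane-spanning stretch (1-based inclusive residues)."""

    start_aa: int
    end_aa: int
    mean_hydropathy: float

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1


def _scores(peptide: str) -> np.ndarray:
    vals = []
    for aa in peptide.upper():
        if aa not in KYTE_DOOLITTLE:
            logger.warning("non-standard residue %r scored as hydropathy 0", aa)
            vals.append(0.0)
        else:
            vals.append(KYTE_DOOLITTLE[aa])
    return np.asarray(vals)


def hydropathy_profile(peptide: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Mean hydropathy of each length-``window`` window (index i = window
    starting at residue i+1)."""
    s = _scores(peptide)
    if len(s) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(s, kernel, mode="valid")


def call_tm_segments(
    peptide: str,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> list[TMSegment]:
    """Predict transmembrane segments from the windowed hydropathy profile.

    Maximal runs of windows whose mean exceeds ``threshold`` become segments
    spanning the union of their windows; after boundary resolution, segments
    shorter than ``min_segment`` residues are dropped.
    """
    n = len(peptide)
    if n < window:
        logger.info("peptide of %d aa shorter than window %d; no TM call", n, window)
        return []
    prof = hydropathy_profile(peptide, window)
    above = prof > threshold

    # maximal runs of above-threshold window start indices (0-based)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    # union span of each run, 1-based residues
    spans = [(a + 1, b + window) for a, b in runs]

    # split overlaps between neighbouring runs at the midpoint
    resolved: list[list[int]] = []
    for s, e in spans:
        if resolved and s <= resolved[-1][1]:
            mid = (s + resolved[-1][1]) // 2
            resolved[-1][1] = mid
            s = mid + 1
        resolved.append([s, e])

    scores = _scores(peptide)
    segments = [
        TMSegment(s, e, float(np.mean(scores[s - 1 : e])))
        for s, e in resolved
        if e - s + 1 >= min_segment
    ]
    return segments


def is_candidate_iia(
    orf: Union[str, "object"],
    min_aa: int = CANDIDATE_LENGTH_RANGE[0],
    max_aa: int = CANDIDATE_LENGTH_RANGE[1],
    **tm_kwargs,
) -> tuple[bool, str]:
    """Subunit-IIa candidacy: exactly one TM segment and length in [min, max].

    Accepts a peptide string or any object with ``peptide``/``length_aa``
    attributes (e.g. an OrfCandidate).  Returns (verdict, reason).
    """
    if isinstance(orf, str):
        peptide, length = orf, len(orf)
    else:
        peptide, length = orf.peptide, orf.length_aa
    if not (min_aa <= length <= max_aa):
        return False, f"length outside [{min_aa},{max_aa}] ({length} aa)"
    segments = call_tm_segments(peptide, **tm_kwargs)
    if len(segments) == 0:
        return False, "no transmembrane segment"
    if len(segments) > 1:
        return False, f"{len(segments)} transmembrane segments (expected exactly 1)"
    return True, "single transmembrane segment, length in range"
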