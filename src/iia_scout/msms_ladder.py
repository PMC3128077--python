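"""Theoretical b/y fragment series and y-ion ladder sequence readout.

Consecutive y ions of a peptide differ by exactly one residue mass, so a
contiguous y-ion series read from low to high m/z spells the sequence from
the C terminus.  At the ~0.5 Da matching tolerance of manually assigned
MALDI TOF/TOF spectra, Ile/Leu (identical residue mass) and Lys/Gln
(0.036 Da apart) cannot be told apart, so readouts carry ambiguity sets
rather than a single guessed residue.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .mass_core import PROTON, RESIDUE_MASS, WATER, Peak, peptide_mass

logger = logging.getLogger(__name__)

_MONO = RESIDUE_MASS["mono"]

__all__ = [
    "FragmentLadder",
    "LadderRun",
    "LadderReadout",
    "fragment_mz_series",
    "read_ladder",
    "read_mgf",
    "write_readout_json",
]


@dataclass
class FragmentLadder:
    series: str  # "b" or "y"
    entries: list[tuple[int, float]]  # (index, m/z), index strictly increasing


@dataclass
class LadderRun:
    """One contiguous stretch of residue calls.

    ``residues`` pairs a position counted from the C terminus with the set of
    residues compatible with the observed mass difference.  Positions are
    absolute when the run is anchored at y1 (its lowest peak matches
    residue + H2O + proton); otherwise they are offsets within the run.
    """

    residues: list[tuple[int, frozenset]]
    rms_error: float
    anchored: bool
    first_peak_mz: float
    last_peak_mz: float


@dataclass
class LadderReadout:
    runs: list[LadderRun]

    @property
    def residues(self) -> list[tuple[int, frozenset]]:
        """Residue calls of the longest run (the primary readout)."""
        if not self.runs:
            return []
        return max(self.runs, key=lambda r: len(r.residues)).residues

    @property
    def rms_error(self) -> Optional[float]:
        if not self.runs:
            return None
        return max(self.runs, key=lambda r: len(r.residues)).rms_error


def fragment_mz_series(peptide: str, series: str = "y") -> FragmentLadder:
    """Singly protonated monoisotopic b- or y-ion m/z values, n = 1..len-1."""
    peptide = peptide.upper()
    if len(peptide) < 2:
        raise ValueError("peptide must have at least 2 residues")
    for aa in peptide:
        if aa not in _MONO:
            raise ValueError(f"non-standard residue {aa!r}")
    if series not in ("b", "y"):
        raise ValueError("series must be 'b' or 'y'")
    entries = []
    if series == "y":
        acc = WATER["mono"] + PROTON
        for n in range(1, len(peptide)):
            acc += _MONO[peptide[len(peptide) - n]]
            entries.append((n, acc))
    else:
        acc = PROTON
        for n in range(1, len(peptide)):
            acc += _MONO[peptide[n - 1]]
            entries.append((n, acc))
    return FragmentLadder(series=series, entries=entries)


def _residues_within(diff: float, tol: float) -> frozenset:
    hits = {aa for aa, m in _MONO.items() if abs(diff - m) <= tol}
    if hits & {"I", "L"}:
        hits |= {"I", "L"}
    return frozenset(hits)


def _nearest_error(diff: float) -> float:
    return min(abs(diff - m) for m in _MONO.values())


def read_ladder(peaks: Sequence[Peak], tolerance_da: float = 0.5) -> LadderReadout:
    """Infer residue identities from successive y-ion mass differences.

    Peaks are sorted by m/z; each successive difference is matched against
    the 20 residue monoisotopic masses within ``tolerance_da``.  Maximal
    contiguous runs of matched differences (at least 2) are reported; when a
    run's lowest peak itself matches residue + H2O + proton, the C-terminal
    residue is included and positions are absolute from the C terminus.
    """
    if len(peaks) < 3:
        raise ValueError("need at least 3 peaks to read a ladder")
    mz = sorted(p.mz for p in peaks)
    diffs = np.diff(mz)
    matched = [_residues_within(d, tolerance_da) for d in diffs]

    runs: list[LadderRun] = []
    i = 0
    while i < len(diffs):
        if matched[i]:
            j = i
            while j + 1 < len(diffs) and matched[j + 1]:
                j += 1
            if j - i + 1 >= 2:
                runs.append(_build_run(mz, diffs, matched, i, j, tolerance_da))
            i = j + 1
        else:
            i += 1
    if not runs:
        logger.info("no contiguous run of >= 2 matched y-ion differences")
    return LadderReadout(runs=runs)


def _build_run(mz, diffs, matched, i, j, tol) -> LadderRun:
    errors = []
    residues: list[tuple[int, frozenset]] = []
    # anchor: does the run's lowest peak look like y1 (residue + water + proton)?
    y1_mass = mz[i] - WATER["mono"] - PROTON
    anchor_set = _residues_within(y1_mass, tol)
    anchored = bool(anchor_set)
    base = 1 if anchored else 0
    if anchored:
        residues.append((1, anchor_set))
        errors.append(_nearest_error(y1_mass))
    for k in range(i, j + 1):
        residues.append((base + (k - i) + 1, matched[k]))
        errors.append(_nearest_error(float(diffs[k])))
    rms = float(np.sqrt(np.mean(np.square(errors))))
    return LadderRun(
        residues=residues,
        rms_error=rms,
        anchored=anchored,
        first_peak_mz=float(mz[i]),
        last_peak_mz=float(mz[j + 1]),
    )


def read_mgf(path: str | Path) -> list[Peak]:
    """Read the first spectrum of an MGF file as a peak list."""
    from pyteomics import mgf

    with mgf.read(str(path)) as reader:
        spectrum = next(iter(reader))
    return [
        Peak(mz=float(m), intensity=float(i))
        for m, i in zip(spectrum["m/z array"], spectrum["intensity array"])
    ]


def write_readout_json(readout: LadderReadout, path: str | Path) -> None:
    payload = {
        "runs": [
            {
                "anchored": r.anchored,
                "rms_error": round(r.rms_error, 4),
                "first_peak_mz": round(r.first_peak_mz, 4),
                "last_peak_mz": round(r.last_peak_mz, 4),
                "residues": [
                    {"position_from_C": pos, "residues": sorted(s)}
                    for pos, s in r.residues
                ],
            }
            for r in readout.runs
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
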