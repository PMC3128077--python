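"""Peptide/protein mass arithmetic and intact-mass peak assignment.

Masses are computed from residue elemental compositions against an IUPAC
element table shipped as package data.  Observed MALDI peaks (z = 1) are
explained by hypotheses combining a charge carrier ([M+H]+ or [M+Na]+) with
neutral losses (NH3) and adducts (acetyl), accepted within a ppm tolerance.
Reflectron-mode peaks are monoisotopic; linear-mode peaks of intact proteins
are average-mass, so both mass modes are supported throughout.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "SpeciesHypothesis",
    "MassAssignment",
    "PeakAssignments",
    "PROTON",
    "SODIUM_ION",
    "NH3",
    "ACETYL",
    "WATER",
    "RESIDUE_MASS",
    "peptide_mass",
    "mz_of_species",
    "ppm_delta",
    "enumerate_hypotheses",
    "assign_peaks",
    "read_peaks_tsv",
    "write_peaks_tsv",
    "write_assignments_tsv",
]


def _load_json(name: str) -> dict:
    with resources.files("iia_scout.data").joinpath(name).open() as fh:
        return json.load(fh)


_ELEMENTS = {k: v for k, v in _load_json("elements.json").items() if k != "comment"}
_RESIDUE_FORMULAS = {
    k: v for k, v in _load_json("residues.json").items() if k != "comment"
}


def _formula_mass(formula: dict, mode: str) -> float:
    return sum(n * _ELEMENTS[el][mode] for el, n in formula.items())


#: residue masses by mode, derived once from the element table
RESIDUE_MASS = {
    mode: {aa: _formula_mass(f, mode) for aa, f in _RESIDUE_FORMULAS.items()}
    for mode in ("mono", "avg")
}

_MODE_KEY = {"monoisotopic": "mono", "average": "avg"}

WATER = {m: _formula_mass({"H": 2, "O": 1}, m) for m in ("mono", "avg")}
NH3 = {m: _formula_mass({"N": 1, "H": 3}, m) for m in ("mono", "avg")}
ACETYL = {m: _formula_mass({"C": 2, "H": 2, "O": 1}, m) for m in ("mono", "avg")}

ELECTRON = 0.00054858
PROTON = 1.007276
#: sodium cation: atomic Na minus one electron
SODIUM_ION = _ELEMENTS["Na"]["mono"] - ELECTRON

_CARRIER = {"protonated": PROTON, "sodiated": SODIUM_ION}


@dataclass
class Peak:
    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


@dataclass(frozen=True)
class SpeciesHypothesis:
    """A candidate explanation of a singly charged peak."""

    base: str = "protonated"  # {"protonated", "sodiated"}
    n_nh3_loss: int = 0
    n_acetyl: int = 0
    mass_mode: str = "monoisotopic"  # {"monoisotopic", "average"}

    def __post_init__(self) -> None:
        if self.base not in _CARRIER:
            raise ValueError(f"unknown charge carrier {self.base!r}")
        if self.mass_mode not in _MODE_KEY:
            raise ValueError(f"unknown mass mode {self.mass_mode!r}")

    @property
    def label(self) -> str:
        s = "[M+H]+" if self.base == "protonated" else "[M+Na]+"
        if self.n_nh3_loss:
            s += f" -{self.n_nh3_loss}xNH3" if self.n_nh3_loss > 1 else " -NH3"
        if self.n_acetyl:
            s += f" +{self.n_acetyl}xacetyl" if self.n_acetyl > 1 else " +acetyl"
        return s


@dataclass
class MassAssignment:
    peak: Peak
    candidate: str
    hypothesis: SpeciesHypothesis
    theoretical_mz: float
    delta_ppm: float


@dataclass
class PeakAssignments:
    """Best assignment per peak, with the full within-tolerance list retained."""

    best: list[MassAssignment]
    all: list[MassAssignment]

    def __iter__(self):
        return iter(self.best)

    def __len__(self) -> int:
        return len(self.best)


def peptide_mass(peptide: str, mode: str = "monoisotopic") -> float:
    """Neutral, uncharged mass: sum of residue masses plus one water."""
    if mode not in _MODE_KEY:
        raise ValueError(f"unknown mass mode {mode!r}")
    if not peptide:
        raise ValueError("empty peptide")
    key = _MODE_KEY[mode]
    table = RESIDUE_MASS[key]
    total = WATER[key]
    for aa in peptide.upper():
        if aa not in table:
            raise ValueError(f"cannot compute mass for residue {aa!r}")
        total += table[aa]
    return total


def mz_of_species(neutral_mass: float, hypothesis: SpeciesHypothesis) -> float:
    """Theoretical m/z at z=1 for the given carrier/loss/adduct combination."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    key = _MODE_KEY[hypothesis.mass_mode]
    return (
        neutral_mass
        + _CARRIER[hypothesis.base]
        - hypothesis.n_nh3_loss * NH3[key]
        + hypothesis.n_acetyl * ACETYL[key]
    )


def ppm_delta(observed: float, theoretical: float) -> float:
    """Signed relative deviation, (obs - theo)/theo * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def enumerate_hypotheses(
    max_mods: int = 1,
    bases: Sequence[str] = ("protonated", "sodiated"),
    mass_mode: str = "monoisotopic",
) -> list[SpeciesHypothesis]:
    """All carrier x loss-count x adduct-count combinations, each modification
    type applied at most ``max_mods`` times."""
    return [
        SpeciesHypothesis(base=b, n_nh3_loss=nl, n_acetyl=na, mass_mode=mass_mode)
        for b in bases
        for nl in range(max_mods + 1)
        for na in range(max_mods + 1)
    ]


def assign_peaks(
    peaks: Sequence[Peak],
    candidates: Sequence[tuple[str, Union[str, float]]],
    tolerance_ppm: float = 150.0,
    max_mods: int = 1,
    mass_mode: str = "monoisotopic",
    bases: Sequence[str] = ("protonated", "sodiated"),
) -> PeakAssignments:
    """Explain each peak by the best within-tolerance species hypothesis.

    ``candidates`` pairs a name with either a peptide sequence or a
    precomputed neutral mass.  For each peak, every (candidate, hypothesis)
    pair within ``tolerance_ppm`` is retained, ranked by absolute ppm
    deviation; the closest one is the reported assignment for that peak.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    masses: list[tuple[str, float]] = []
    for name, p in candidates:
        masses.append((name, peptide_mass(p, mass_mode) if isinstance(p, str) else float(p)))
    hypotheses = enumerate_hypotheses(max_mods=max_mods, bases=bases, mass_mode=mass_mode)

    best: list[MassAssignment] = []
    everything: list[MassAssignment] = []
    for peak in peaks:
        matches = []
        for (name, m), hyp in itertools.product(masses, hypotheses):
            theo = mz_of_species(m, hyp)
            d = ppm_delta(peak.mz, theo)
            if abs(d) <= tolerance_ppm:
                matches.append(MassAssignment(peak, name, hyp, theo, d))
        matches.sort(key=lambda a: abs(a.delta_ppm))
        everything.extend(matches)
        if matches:
            best.append(matches[0])
    return PeakAssignments(best=best, all=everything)


def read_peaks_tsv(path: str | Path) -> list[Peak]:
    """Two-column TSV (mz, intensity); a header line is detected and skipped."""
    peaks = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        try:
            mz = float(parts[0])
        except ValueError:
            if i == 0:
                continue  # header
            raise
        inten = float(parts[1]) if len(parts) > 1 else 0.0
        peaks.append(Peak(mz=mz, intensity=inten))
    return peaks


def write_peaks_tsv(peaks: Sequence[Peak], path: str | Path) -> None:
    lines = ["mz\tintensity"] + [f"{p.mz:.6f}\t{p.intensity:.4f}" for p in peaks]
    Path(path).write_text("\n".join(lines) + "\n")


def write_assignments_tsv(assignments: Iterable[MassAssignment], path: str | Path) -> None:
    lines = ["peak_mz\tcandidate\tcarrier\tmods\ttheo_mz\tdelta_ppm"]
    for a in assignments:
        mods = []
        if a.hypothesis.n_nh3_loss:
            mods.append(f"-{a.hypothesis.n_nh3_loss}NH3")
        if a.hypothesis.n_acetyl:
            mods.append(f"+{a.hypothesis.n_acetyl}acetyl")
        lines.append(
            f"{a.peak.mz:.4f}\t{a.candidate}\t{a.hypothesis.base}\t"
            f"{','.join(mods) or '-'}\t{a.theoretical_mz:.4f}\t{a.delta_ppm:.2f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
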