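"""Synthetic operon genomes and MALDI spectra with known planted truth.

The operon generator emulates the genomic situation in which subunit IIa was
found: an anchor subunit-II gene with an intergenic region directly 5' of it
containing a small single-TM-helix ORF, optionally left out of the GFF
(the unannotated case) and optionally disrupted by a planted single-base
insertion inside the anchor gene (the sequencing-error case).  Background and
intergenic filler are drawn from {C,G} only, so no start or stop codons — and
hence no spurious ORFs — arise outside the planted genes; real intergenic DNA
is of course not GC-only, which is a deliberate idealization (see the methods
note).  Hydrophobic cores use {L,I,V,F} and flanks hydrophilic residues so
hydropathy calls never sit on the threshold.

The spectrum generator plants [M+H]+/[M+Na]+ species with NH3-loss and
acetyl satellites under multiplicative ppm calibration error, plus noise
peaks kept >= 500 ppm away from every planted species, and y-ion ladders
under additive Da scatter.

All outputs are deterministic functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .mass_core import Peak, SpeciesHypothesis, mz_of_species, peptide_mass
from .msms_ladder import fragment_mz_series
from .seqio import GeneAnnotation, GenomeRecord

HYDROPHOBIC = "LIVF"
HYDROPHILIC = "EDKNQ"
_FILLER = "CG"

# codon choices per residue restricted to unambiguous, start/stop-free options
_CODON = {
    "L": ("CTC", "CTG"), "I": ("ATC", "ATT"), "V": ("GTC",), "F": ("TTC", "TTT"),
    "E": ("GAA", "GAG"), "D": ("GAC", "GAT"), "K": ("AAA", "AAG"),
    "N": ("AAC", "AAT"), "Q": ("CAA", "CAG"), "S": ("AGC", "TCC"),
    "P": ("CCA", "CCG"), "G": ("GGC", "GGA"), "T": ("ACC", "ACA"),
    "A": ("GCC", "GCA"), "W": ("TGG",), "M": ("ATG",),
    "R": ("CGC",), "H": ("CAC",), "Y": ("TAC",), "C": ("TGC",),
}

__all__ = [
    "OperonSpec",
    "SpectrumSpec",
    "SimulatedOperon",
    "SimulatedSpectra",
    "simulate_operon_genome",
    "simulate_spectra",
]


@dataclass(frozen=True)
class OperonSpec:
    """Parameters of a planted oxidase-operon neighbourhood."""

    anchor_len_aa: int = 150
    iia_len_aa: int = 41
    iia_tm_core_len: int = 19
    intergenic_len: int = 300
    frameshift: Optional[tuple[int, str]] = None  # (nt offset in anchor CDS, base)
    seed: int = 0
    iia_with_motif: bool = True
    iia_annotated: bool = False
    anchor_cores: int = 1
    flank_len: int = 150  # background on each side of the operon

    def __post_init__(self) -> None:
        if self.iia_len_aa < self.iia_tm_core_len + 4:
            raise ValueError("iia_len_aa must be >= iia_tm_core_len + 4")
        if self.anchor_cores not in (1, 2):
            raise ValueError("anchor_cores must be 1 or 2")


@dataclass(frozen=True)
class SpectrumSpec:
    """Parameters of a planted MS1/MSMS spectrum pair."""

    species: tuple[tuple[SpeciesHypothesis, float], ...] = (
        (SpeciesHypothesis(base="protonated"), 1.0),
        (SpeciesHypothesis(base="protonated", n_nh3_loss=1), 0.30),
        (SpeciesHypothesis(base="protonated", n_acetyl=1), 0.25),
        (SpeciesHypothesis(base="sodiated"), 0.40),
    )
    ppm_jitter: float = 80.0
    noise_peaks: int = 10
    msms_da_jitter: float = 0.3
    drop_y_ions: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_jitter < 0 or self.msms_da_jitter < 0:
            raise ValueError("jitters must be non-negative")


@dataclass
class SimulatedOperon:
    genome: GenomeRecord
    annotations: list[GeneAnnotation]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "operon.fasta"
        gff = outdir / "operon.gff3"
        truth = outdir / "truth.json"
        seq = self.genome.sequence
        lines = [f">{self.genome.id}"]
        lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
        fasta.write_text("\n".join(lines) + "\n")
        gff_lines = ["##gff-version 3"]
        for a in self.annotations:
            gff_lines.append(
                "\t".join(
                    [
                        a.genome_id, "iia_scout", "gene",
                        str(a.start), str(a.end), ".", a.strand, ".",
                        f"ID={a.gene_id};role={a.role}",
                    ]
                )
            )
        gff.write_text("\n".join(gff_lines) + "\n")
        truth.write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        return {"fasta": fasta, "gff": gff, "truth": truth}


@dataclass
class SimulatedSpectra:
    ms1_peaks: list[Peak]
    msms_peaks: list[Peak]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from pyteomics import mgf

        from .mass_core import write_peaks_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ms1 = outdir / "ms1.tsv"
        msms = outdir / "msms.mgf"
        truth = outdir / "truth.json"
        write_peaks_tsv(self.ms1_peaks, ms1)
        spectrum = {
            "m/z array": np.array([p.mz for p in self.msms_peaks]),
            "intensity array": np.array([p.intensity for p in self.msms_peaks]),
            "params": {"title": "synthetic y-ion ladder", "charge": "1+", "pepmass": 0.0},
        }
        mgf.write([spectrum], str(msms), file_mode="w")
        truth.write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        return {"ms1": ms1, "mgf": msms, "truth": truth}


def _pick(rng: np.random.Generator, pool: str) -> str:
    return pool[int(rng.integers(len(pool)))]


def _codons(rng: np.random.Generator, peptide: str) -> str:
    return "".join(_CODON[aa][int(rng.integers(len(_CODON[aa])))] for aa in peptide)


def _filler(rng: np.random.Generator, n: int) -> str:
    """Intergenic/background filler: {C,G} with interspersed TAA/TAG stops.

    The stops keep every reading frame closed (no spurious ORFs bridging the
    filler), while the construction admits no ATG/GTG/TTG anywhere: TT never
    occurs, and stop triplets are flanked by C/G with >=2 spacer bases.
    """
    out: list[str] = []
    gap_since_stop = 2
    while len(out) < n:
        if gap_since_stop >= 2 and len(out) + 3 <= n - 2 and rng.random() < 0.06:
            out.extend(("TAA", "TAG")[int(rng.integers(2))])
            gap_since_stop = 0
        else:
            out.append(_pick(rng, _FILLER))
            gap_since_stop += 1
    return "".join(out)


def _hydrophilic(rng: np.random.Generator, n: int) -> str:
    return "".join(_pick(rng, HYDROPHILIC) for _ in range(n))


def _core(rng: np.random.Generator, n: int) -> str:
    return "".join(_pick(rng, HYDROPHOBIC) for _ in range(n))


def _iia_peptide(rng: np.random.Generator, spec: OperonSpec) -> dict:
    """Layout: M | hydrophilic | [PxxGT motif] | hydrophilic | core | hydrophilic+W."""
    L, k = spec.iia_len_aa, spec.iia_tm_core_len
    motif = ("P" + _hydrophilic(rng, 2) + "GT") if spec.iia_with_motif else _hydrophilic(rng, 5)
    head = "M" + _hydrophilic(rng, 3) + motif + _hydrophilic(rng, 2)
    tail_len = L - len(head) - k
    if tail_len < 4:
        raise ValueError("iia_len_aa too short for motif + core layout")
    tail = list(_hydrophilic(rng, tail_len))
    tail[min(2, tail_len - 1)] = "W"  # the conserved Trp, C-terminal of the core
    peptide = head + _core(rng, k) + "".join(tail)
    assert len(peptide) == L
    return {
        "peptide": peptide,
        "motif_start": 5 if spec.iia_with_motif else None,
        "core_span": [len(head) + 1, len(head) + k],
    }


def _anchor_flank(rng: np.random.Generator, n: int) -> str:
    # mostly hydrophilic with ~15% scattered hydrophobic singles: realistic
    # soluble-domain composition; far below the 19-window hydropathy
    # threshold, yet frame-shifted readings hit stop codons promptly
    return "".join(
        _pick(rng, HYDROPHOBIC) if rng.random() < 0.15 else _pick(rng, HYDROPHILIC)
        for _ in range(n)
    )


def _anchor_peptide(rng: np.random.Generator, spec: OperonSpec) -> str:
    L = spec.anchor_len_aa
    core = 19
    if spec.anchor_cores == 1:
        pre = max(4, (L - core) // 3)
        post = L - 1 - pre - core
        return "M" + _anchor_flank(rng, pre) + _core(rng, core) + _anchor_flank(rng, post)
    gap = 12
    rest = L - 1 - 2 * core - gap
    pre = max(4, rest // 2)
    post = rest - pre
    return (
        "M"
        + _anchor_flank(rng, pre)
        + _core(rng, core)
        + _hydrophilic(rng, gap)
        + _core(rng, core)
        + _anchor_flank(rng, post)
    )


def simulate_operon_genome(spec: OperonSpec) -> SimulatedOperon:
    """Emit a genome with gene order: [bg] IIa-ORF [gap] anchor [bg] on '+'.

    The generated FASTA/GFF always satisfy the loader's validation, and the
    truth dict records all planted coordinates, peptides, and any indel
    position.  A post-check re-derives the candidate set and retries with a
    perturbed stream (still a pure function of the seed) in the vanishingly
    rare event that a shifted-frame ORF also passes the candidacy filter.
    """
    from .orf_hunter import scan_small_orfs
    from .tm_hydropathy import is_candidate_iia

    iia_nt = 3 * spec.iia_len_aa + 3  # incl. stop
    if spec.intergenic_len < iia_nt + 20:
        raise ValueError(
            f"intergenic_len {spec.intergenic_len} cannot hold a "
            f"{spec.iia_len_aa}-codon ORF plus spacers"
        )

    for attempt in range(40):
        rng = np.random.default_rng((spec.seed, attempt))
        iia = _iia_peptide(rng, spec)
        anchor_pep = _anchor_peptide(rng, spec)

        iia_cds = _codons(rng, iia["peptide"]) + "TAA"
        anchor_cds = _codons(rng, anchor_pep) + "TAA"
        if spec.frameshift is not None:
            off, base = spec.frameshift
            if not (0 < off < len(anchor_cds)):
                raise ValueError("frameshift offset outside the anchor CDS")
            anchor_cds_mut = anchor_cds[:off] + base + anchor_cds[off:]
        else:
            anchor_cds_mut = anchor_cds

        pre_gap = (spec.intergenic_len - iia_nt) // 2
        post_gap = spec.intergenic_len - iia_nt - pre_gap
        left = _filler(rng, spec.flank_len)
        right = _filler(rng, spec.flank_len)
        seq = left + _filler(rng, pre_gap) + iia_cds + _filler(rng, post_gap)
        anchor_start = len(seq) + 1
        seq += anchor_cds_mut + right

        iia_start = spec.flank_len + pre_gap + 1
        iia_end = iia_start + iia_nt - 1
        genome = GenomeRecord(id=f"synthetic_operon_{spec.seed}", sequence=seq)
        anchor_end = anchor_start + len(anchor_cds_mut) - 1
        annotations = [
            GeneAnnotation(
                gene_id="coxB2",
                genome_id=genome.id,
                start=anchor_start,
                end=anchor_end,
                strand="+",
                role="anchor_subunit_II",
            )
        ]
        if spec.iia_annotated:
            annotations.insert(
                0,
                GeneAnnotation(
                    gene_id="coxIIa",
                    genome_id=genome.id,
                    start=iia_start,
                    end=iia_end,
                    strand="+",
                ),
            )

        # post-check: the planted ORF must be the unique passing candidate
        window = seq[max(0, anchor_start - 1 - 750) : anchor_start - 1]
        offset = max(0, anchor_start - 1 - 750) + 1
        cands = scan_small_orfs(window, genome_id=genome.id, offset=offset)
        passing = [c for c in cands if is_candidate_iia(c)[0]]
        planted_ok = any(
            c.start == iia_start and c.end == iia_end and c.peptide == iia["peptide"]
            for c in passing
        )
        fs_ok = True
        if spec.frameshift is not None:
            # A one-base indel is localizable only up to the surrounding
            # frame-ambiguous (stop-free under shift) stretch; re-draw codons
            # until the planted insert is the leftmost top-scoring run, so the
            # planted truth is actually recoverable from the sequence alone.
            from .orf_hunter import detect_frameshift

            region = seq[spec.flank_len : anchor_end]
            calls = detect_frameshift(region, offset=spec.flank_len + 1)
            pos = anchor_start + spec.frameshift[0]
            fs_ok = bool(calls) and calls[0].run_start <= pos <= calls[0].run_end
        if planted_ok and len(passing) == 1 and fs_ok:
            break
    else:  # pragma: no cover - generator construction precludes this
        raise RuntimeError("could not generate an unambiguous operon")

    truth = {
        "seed": spec.seed,
        "genome_id": genome.id,
        "iia": {
            "start": iia_start,
            "end": iia_end,
            "strand": "+",
            "peptide": iia["peptide"],
            "length_aa": spec.iia_len_aa,
            "motif_start": iia["motif_start"],
            "core_span": iia["core_span"],
            "annotated": spec.iia_annotated,
        },
        "anchor": {
            "gene_id": "coxB2",
            "start": anchor_start,
            "end": anchor_end,
            "strand": "+",
            "peptide": anchor_pep,
            "cores": spec.anchor_cores,
        },
    }
    if spec.frameshift is not None:
        off, base = spec.frameshift
        truth["frameshift"] = {
            "inserted_base": base,
            "position": anchor_start + off,  # 1-based genome position of the insert
            "anchor_cds_offset": off,
        }
    return SimulatedOperon(genome=genome, annotations=annotations, truth=truth)


def simulate_spectra(peptide: str, spec: SpectrumSpec) -> SimulatedSpectra:
    """Plant MS1 species and an MS/MS y-ion ladder for ``peptide``."""
    rng = np.random.default_rng(spec.seed)
    neutral = {
        "monoisotopic": peptide_mass(peptide, "monoisotopic"),
        "average": peptide_mass(peptide, "average"),
    }
    ms1: list[Peak] = []
    truth_species = []
    theo_all = []
    for hyp, abundance in spec.species:
        theo = mz_of_species(neutral[hyp.mass_mode], hyp)
        eps = rng.uniform(-spec.ppm_jitter, spec.ppm_jitter)
        obs = theo * (1 + eps * 1e-6)
        ms1.append(Peak(mz=obs, intensity=abundance * 1000.0))
        theo_all.append(theo)
        truth_species.append(
            {
                "label": hyp.label,
                "base": hyp.base,
                "n_nh3_loss": hyp.n_nh3_loss,
                "n_acetyl": hyp.n_acetyl,
                "mass_mode": hyp.mass_mode,
                "theoretical_mz": round(theo, 6),
                "observed_mz": round(obs, 6),
            }
        )

    # noise must stay >= 500 ppm away from EVERY enumerable hypothesis (not
    # just the planted ones), so that no noise peak is assignable
    from .mass_core import enumerate_hypotheses

    guard = list(theo_all)
    for mode in {h.mass_mode for h, _ in spec.species}:
        for hyp in enumerate_hypotheses(max_mods=1, mass_mode=mode):
            guard.append(mz_of_species(neutral[mode], hyp))
    lo = min(theo_all) * 0.95
    hi = max(theo_all) * 1.05
    noise = []
    while len(noise) < spec.noise_peaks:
        x = rng.uniform(lo, hi)
        if all(abs(x - t) / t * 1e6 >= 500.0 for t in guard):
            noise.append(x)
            ms1.append(Peak(mz=x, intensity=float(rng.uniform(10, 80))))

    ladder = fragment_mz_series(peptide, "y")
    msms = []
    msms_truth = []
    # MALDI mass error is dominated by smooth miscalibration: model it as a
    # per-spectrum offset (2/3 of the amplitude) plus a small per-peak
    # residual (1/3), so successive y-ion differences carry only the residual.
    offset = rng.uniform(-2.0 / 3.0, 2.0 / 3.0) * spec.msms_da_jitter
    for n, mz in ladder.entries:
        if n in spec.drop_y_ions:
            continue
        obs = mz + offset + rng.uniform(-1.0 / 3.0, 1.0 / 3.0) * spec.msms_da_jitter
        msms.append(Peak(mz=obs, intensity=float(rng.uniform(100, 1000))))
        msms_truth.append({"index": n, "theoretical_mz": round(mz, 6), "observed_mz": round(obs, 6)})

    truth = {
        "seed": spec.seed,
        "peptide": peptide,
        "neutral_mass": {k: round(v, 6) for k, v in neutral.items()},
        "ms1_species": truth_species,
        "noise_mz": [round(x, 6) for x in noise],
        "y_ions": msms_truth,
    }
    return SimulatedSpectra(ms1_peaks=ms1, msms_peaks=msms, truth=truth)
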