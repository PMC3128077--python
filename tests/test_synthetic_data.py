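import json

import pytest

from iia_scout.mass_core import assign_peaks
from iia_scout.motif_align import scan_motif
from iia_scout.msms_ladder import read_ladder, read_mgf
from iia_scout.orf_hunter import detect_frameshift, scan_small_orfs
from iia_scout.seqio import load_annotated_genome
from iia_scout.synthetic_data import (
    OperonSpec,
    SpectrumSpec,
    simulate_operon_genome,
    simulate_spectra,
)
from iia_scout.tm_hydropathy import call_tm_segments, is_candidate_iia


class TestSimulateOperonGenome:
    def test_planted_orf_recovered_verbatim(self):
        op = simulate_operon_genome(OperonSpec(seed=1))
        truth = op.truth["iia"]
        anchor = next(a for a in op.annotations if a.gene_id == "coxB2")
        w0 = max(0, anchor.start - 1 - 750)
        window = op.genome.sequence[w0 : anchor.start - 1]
        cands = scan_small_orfs(window, offset=w0 + 1)
        match = [c for c in cands if is_candidate_iia(c)[0]]
        assert len(match) == 1
        assert (match[0].start, match[0].end, match[0].peptide) == (
            truth["start"], truth["end"], truth["peptide"],
        )

    def test_planted_motif_and_core_are_present(self):
        op = simulate_operon_genome(OperonSpec(seed=2))
        truth = op.truth["iia"]
        hits = scan_motif(truth["peptide"])
        assert any(h.position == truth["motif_start"] for h in hits)
        (seg,) = call_tm_segments(truth["peptide"])
        lo, hi = truth["core_span"]
        assert seg.start_aa <= lo and seg.end_aa >= hi

    def test_frameshift_truth_in_top_ranked_run(self):
        op = simulate_operon_genome(OperonSpec(seed=3, frameshift=(210, "A")))
        anchor = next(a for a in op.annotations if a.gene_id == "coxB2")
        region = op.genome.sequence[150 : anchor.end]
        calls = detect_frameshift(region, offset=151)
        pos = op.truth["frameshift"]["position"]
        assert calls and calls[0].run_start <= pos <= calls[0].run_end

    def test_same_seed_byte_identical(self, tmp_path):
        a = simulate_operon_genome(OperonSpec(seed=5)).write(tmp_path / "a")
        b = simulate_operon_genome(OperonSpec(seed=5)).write(tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_outputs_pass_loader_validation(self, tmp_path):
        paths = simulate_operon_genome(OperonSpec(seed=6, iia_annotated=True)).write(tmp_path)
        genomes, anns = load_annotated_genome(paths["fasta"], paths["gff"])
        assert genomes[0].length == len(
            simulate_operon_genome(OperonSpec(seed=6, iia_annotated=True)).genome.sequence
        )
        assert {a.gene_id for a in anns} == {"coxIIa", "coxB2"}

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            simulate_operon_genome(OperonSpec(intergenic_len=100, iia_len_aa=41))
        with pytest.raises(ValueError):
            OperonSpec(iia_len_aa=20, iia_tm_core_len=19)


class TestSimulateSpectra:
    PEPTIDE = "MNEKHPAAGTWDKELIVFLLIVAGFSAILKENQDKW"

    def test_zero_jitter_species_recovered_exactly(self):
        spec = SpectrumSpec(ppm_jitter=0.0, noise_peaks=0, seed=1)
        sim = simulate_spectra(self.PEPTIDE, spec)
        res = assign_peaks(sim.ms1_peaks, [("iia", self.PEPTIDE)], tolerance_ppm=150)
        assert len(res.best) == len(spec.species)
        assert all(abs(a.delta_ppm) < 1e-6 for a in res.best)

    def test_jittered_species_recovered_and_noise_unassigned(self):
        spec = SpectrumSpec(ppm_jitter=80.0, noise_peaks=20, seed=7)
        sim = simulate_spectra(self.PEPTIDE, spec)
        res = assign_peaks(sim.ms1_peaks, [("iia", self.PEPTIDE)], tolerance_ppm=150)
        planted = sorted(s["label"] for s in sim.truth["ms1_species"])
        assert sorted(a.hypothesis.label for a in res.best) == planted
        assigned_mz = {a.peak.mz for a in res.best}
        assert assigned_mz.isdisjoint(set(sim.truth["noise_mz"]))

    def test_msms_jitter_readout_matches_truth(self):
        sim = simulate_spectra(self.PEPTIDE, SpectrumSpec(msms_da_jitter=0.3, seed=3))
        readout = read_ladder(sim.msms_peaks, tolerance_da=0.5)
        n = len(self.PEPTIDE)
        assert len(readout.residues) == n - 1
        for pos, residues in readout.residues:
            assert self.PEPTIDE[n - pos] in residues

    def test_dropped_ion_splits_ladder(self):
        sim = simulate_spectra(
            self.PEPTIDE, SpectrumSpec(msms_da_jitter=0.0, drop_y_ions=(12,), seed=4)
        )
        readout = read_ladder(sim.msms_peaks)
        assert len(readout.runs) == 2

    def test_round_trip_through_files(self, tmp_path):
        sim = simulate_spectra(self.PEPTIDE, SpectrumSpec(seed=9))
        paths = sim.write(tmp_path)
        from iia_scout.mass_core import read_peaks_tsv

        assert len(read_peaks_tsv(paths["ms1"])) == len(sim.ms1_peaks)
        mgf_peaks = read_mgf(paths["mgf"])
        assert len(mgf_peaks) == len(sim.msms_peaks)
        truth = json.loads(paths["truth"].read_text())
        assert truth["peptide"] == self.PEPTIDE

    def test_seeded_determinism(self):
        a = simulate_spectra(self.PEPTIDE, SpectrumSpec(seed=2))
        b = simulate_spectra(self.PEPTIDE, SpectrumSpec(seed=2))
        assert [p.mz for p in a.ms1_peaks] == [p.mz for p in b.ms1_peaks]
        assert [p.mz for p in a.msms_peaks] == [p.mz for p in b.msms_peaks]
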