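import pytest

from iia_scout.seqio import load_annotated_genome
from iia_scout.survey import (
    SurveySummary,
    load_reference_survey,
    survey_genome,
    tabulate_survey,
)
from iia_scout.synthetic_data import OperonSpec, simulate_operon_genome


class TestSurveyGenome:
    def test_annotated_iia_reported_with_planted_coordinates(self):
        op = simulate_operon_genome(OperonSpec(seed=11, iia_annotated=True))
        row = survey_genome(op.genome, op.annotations, "coxB2")
        assert row.iia_status == "annotated"
        assert row.iia_accession == "coxIIa"
        assert row.sub2_tm == 1 and row.iia_tm == 1

    def test_stripped_annotation_is_rediscovered(self):
        annotated = simulate_operon_genome(OperonSpec(seed=11, iia_annotated=True))
        stripped = simulate_operon_genome(OperonSpec(seed=11, iia_annotated=False))
        assert annotated.genome.sequence == stripped.genome.sequence
        row = survey_genome(stripped.genome, stripped.annotations, "coxB2")
        assert row.iia_status == "detected_unannotated"
        truth = stripped.truth["iia"]
        cand = row.iia_candidate
        assert (cand.start, cand.end, cand.peptide) == (
            truth["start"], truth["end"], truth["peptide"],
        )

    def test_two_helix_anchor_without_orf_is_absent(self):
        op = simulate_operon_genome(OperonSpec(seed=12, anchor_cores=2))
        # remove the planted IIa ORF by surveying a genome slice without it
        from iia_scout.seqio import GenomeRecord, GeneAnnotation

        anchor = next(a for a in op.annotations if a.gene_id == "coxB2")
        cut = op.truth["iia"]["end"] + 5  # window upstream of anchor lacks the ORF
        genome = GenomeRecord("trimmed", op.genome.sequence[cut:])
        shifted = GeneAnnotation(
            "coxB2", "trimmed", anchor.start - cut, anchor.end - cut, "+",
            role="anchor_subunit_II",
        )
        row = survey_genome(genome, [shifted], "coxB2")
        assert row.sub2_tm == 2
        assert row.iia_status == "absent"
        assert row.iia_tm is None and row.iia_mm is None

    def test_missing_anchor_raises(self):
        op = simulate_operon_genome(OperonSpec(seed=13))
        with pytest.raises(KeyError):
            survey_genome(op.genome, op.annotations, "nope")

    def test_round_trip_through_fasta_gff(self, tmp_path):
        op = simulate_operon_genome(OperonSpec(seed=14, iia_annotated=True))
        paths = op.write(tmp_path)
        genomes, anns = load_annotated_genome(paths["fasta"], paths["gff"])
        row = survey_genome(genomes[0], anns, "coxB2")
        assert row.iia_status == "annotated"


class TestTabulateSurvey:
    def test_published_survey_counts(self):
        rows = load_reference_survey()
        table, summary = tabulate_survey(rows)
        assert summary.n_regions == 36
        assert summary.n_annotated_iia == 21
        assert summary.n_detected_iia == 6
        assert summary.n_absent == 9
        assert len(table) == 36

    def test_empty_row_list(self):
        table, summary = tabulate_survey([])
        assert len(table) == 0
        assert (summary.n_regions, summary.n_absent) == (0, 0)

    def test_one_of_each_status(self):
        ops = {
            "annotated": simulate_operon_genome(OperonSpec(seed=21, iia_annotated=True)),
            "detected": simulate_operon_genome(OperonSpec(seed=22)),
        }
        rows = [
            survey_genome(op.genome, op.annotations, "coxB2") for op in ops.values()
        ]
        # an absent case: two-helix anchor with the IIa region trimmed away
        from iia_scout.seqio import GenomeRecord, GeneAnnotation

        op = simulate_operon_genome(OperonSpec(seed=23, anchor_cores=2))
        anchor = next(a for a in op.annotations if a.gene_id == "coxB2")
        cut = op.truth["iia"]["end"] + 5
        rows.append(
            survey_genome(
                GenomeRecord("t", op.genome.sequence[cut:]),
                [GeneAnnotation("coxB2", "t", anchor.start - cut, anchor.end - cut, "+")],
                "coxB2",
            )
        )
        _, summary = tabulate_survey(rows)
        assert (summary.n_regions, summary.n_annotated_iia,
                summary.n_detected_iia, summary.n_absent) == (3, 1, 1, 1)

    def test_partition_invariant_enforced(self):
        with pytest.raises(AssertionError):
            SurveySummary(n_regions=3, n_annotated_iia=1, n_detected_iia=1, n_absent=2)

    def test_absent_rows_have_empty_iia_fields(self):
        for row in load_reference_survey():
            if row.iia_status == "absent":
                assert row.iia_accession == "" and row.iia_tm is None and row.iia_mm is None
            else:
                assert row.iia_tm == 1

    def test_sub2_tm_values_are_one_or_two(self):
        assert {r.sub2_tm for r in load_reference_survey()} == {1, 2}
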