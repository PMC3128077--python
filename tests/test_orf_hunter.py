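import pytest

from iia_scout.orf_hunter import (
    EmptyWindowError,
    detect_frameshift,
    interval_codon_count,
    scan_small_orfs,
    upstream_window,
)
from iia_scout.seqio import GeneAnnotation, GenomeRecord, reverse_complement, translate

STARTS = ("ATG", "GTG", "TTG")


def brute_force_orfs(region, min_aa, max_aa, starts=STARTS, all_starts=False):
    """Independent oracle: enumerate every (start codon, first in-frame stop)
    pair in all three frames by direct scanning."""
    region = region.upper()
    found = []
    for frame in range(3):
        codon_pos = list(range(frame, len(region) - 2, 3))
        stops = [i for i in codon_pos if translate(region[i : i + 3]) == "*"]
        for s in codon_pos:
            if region[s : s + 3] not in starts:
                continue
            nxt = [t for t in stops if t > s]
            if not nxt:
                continue  # open-ended: excluded by default
            t = nxt[0]
            pep_len = (t - s) // 3
            if min_aa <= pep_len <= max_aa:
                found.append((s + 1, t + 3, frame))
    if not all_starts:
        by_stop = {}
        for s, e, f in found:
            if e not in by_stop or s < by_stop[e][0]:
                by_stop[e] = (s, e, f)
        found = list(by_stop.values())
    return sorted(found)


class TestUpstreamWindow:
    def _genome(self, n=2000):
        return GenomeRecord("g", "A" * n)

    def test_plus_strand_arithmetic(self):
        ann = GeneAnnotation("a", "g", 1001, 1600, "+")
        assert upstream_window(ann, self._genome(), 500) == (501, 1000, "+")

    def test_minus_strand_flips_direction(self):
        ann = GeneAnnotation("a", "g", 101, 700, "-")
        assert upstream_window(ann, self._genome(), 500) == (701, 1200, "-")

    def test_anchor_at_genome_edge(self):
        ann = GeneAnnotation("a", "g", 1, 300, "+")
        with pytest.raises(EmptyWindowError):
            upstream_window(ann, self._genome(), 500)

    def test_truncated_at_same_strand_gene(self):
        ann = GeneAnnotation("a", "g", 1001, 1600, "+")
        blocker = GeneAnnotation("b", "g", 100, 800, "+")
        assert upstream_window(ann, self._genome(), 500, [blocker]) == (801, 1000, "+")


class TestScanSmallOrfs:
    def test_planted_orf(self):
        region = "C" * 10 + "ATG" + "GCT" * 30 + "TAA" + "C" * 10
        (cand,) = scan_small_orfs(region)
        assert (cand.start, cand.end) == (11, 106)
        assert cand.length_aa == 31 and cand.peptide == "M" + "A" * 30
        assert cand.frame == 1 and not cand.open_ended
        assert cand.codon_count == 32  # incl. stop codon

    def test_no_start_codons_gives_empty(self):
        assert scan_small_orfs("CCC" * 60) == []

    def test_short_region_logs_and_returns_empty(self, caplog):
        with caplog.at_level("INFO"):
            assert scan_small_orfs("ATGAAATAA", min_aa=25) == []

    @pytest.mark.parametrize("length", [300, 997, 2000])
    @pytest.mark.parametrize("all_starts", [False, True])
    def test_matches_brute_force_oracle(self, random_dna, length, all_starts):
        for _ in range(6):
            region = random_dna(length)
            for oriented in (region, reverse_complement(region)):
                got = sorted(
                    (c.start, c.end, c.frame)
                    for c in scan_small_orfs(
                        oriented, min_aa=5, max_aa=100, all_starts=all_starts
                    )
                )
                assert got == brute_force_orfs(oriented, 5, 100, all_starts=all_starts)


class TestIntervalCodonCount:
    def test_published_interval_spans_41_codons(self):
        assert interval_codon_count(1541953, 1542075) == 41

    def test_partial_codon_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_codon_count(1, 5)


SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _clean_orf(n_codons, rng):
    body = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, n_codons - 1))
    return "ATG" + body + "TAA"


class TestDetectFrameshift:
    def test_planted_insertion_recovered(self, rng):
        orf = _clean_orf(90, rng)  # 90 codons -> 90-aa peptide incl. Met
        region = "CCG" * 10 + orf + "TAGA" * 8  # tail carries stops in all frames
        insert_at = 30 + 3 * 45  # after codon 45 of the ORF
        mutated = region[:insert_at] + "A" + region[insert_at:]
        calls = detect_frameshift(mutated, min_gain_aa=20)
        assert calls, "planted insertion must be detected"
        top = calls[0]
        assert top.edit == "delete_1"
        assert top.run_start <= insert_at + 1 <= top.run_end
        assert top.fused_orf.length_aa == 90

    def test_clean_orf_yields_no_calls(self, rng):
        region = "CCG" * 10 + _clean_orf(90, rng) + "GGC" * 10
        assert detect_frameshift(region, min_gain_aa=20) == []

    def test_two_distant_insertions_give_two_runs(self, rng):
        def guarded_orf(n):
            # GAT+AAA right after codon 5: an insertion between codons 5 and
            # 6 hits a shifted-frame stop immediately, so the broken ORF is
            # short and the repair's length gain is decisive
            body = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, n - 8))
            return "ATG" + _clean_orf(5, rng)[3:-3] + "GATAAA" + body + "TAA"

        orf1, orf2 = guarded_orf(60), guarded_orf(60)
        spacer = "TAGA" * 12  # stop codons in all three frames, no start codons
        region = "CCG" * 5 + orf1 + spacer + orf2 + "TAGA" * 8
        # inserts between codons 5 and 6 of each ORF
        p1 = 15 + 3 * 5
        p2 = 15 + len(orf1) + 1 + len(spacer) + 3 * 5
        mutated = region[:p1] + "A" + region[p1:]
        mutated = mutated[:p2] + "A" + mutated[p2:]
        # ATG-only starts: at this small scale incidental GTG/TTG-initiated
        # ORFs in shifted frames otherwise mask the local length gain
        calls = detect_frameshift(mutated, min_gain_aa=30, starts=("ATG",))
        assert len(calls) >= 2
        spans = [(c.run_start, c.run_end) for c in calls]
        assert any(s <= p1 + 1 <= e for s, e in spans)
        assert any(s <= p2 + 1 <= e for s, e in spans)

    def test_region_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_frameshift("ATG" * 10)
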