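"""Micro-ORF discovery upstream of an anchor gene and frameshift detection.

The biological target is the small (~25-100 codon) unannotated gene that, in
B-family heme-copper oxidase operons, sits directly 5' of the subunit II gene
and encodes the single-helix subunit IIa.  A second task of this module is to
flag single-nucleotide insertions that split a reading frame — the class of
genome-sequencing error that truncates annotations — by asking, for every
candidate one-base edit, how much longer the longest open reading frame
covering the edited site becomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from functools import lru_cache

from Bio.Data import CodonTable

from .seqio import GeneAnnotation, GenomeRecord, translate


@lru_cache(maxsize=8)
def _stop_codons(table: int) -> frozenset:
    return frozenset(CodonTable.unambiguous_dna_by_id[table].stop_codons)

logger = logging.getLogger(__name__)

DEFAULT_STARTS = ("ATG", "GTG", "TTG")
DEFAULT_MIN_AA = 25
DEFAULT_MAX_AA = 100
DEFAULT_WINDOW = 750

__all__ = [
    "OrfCandidate",
    "FrameshiftCall",
    "EmptyWindowError",
    "upstream_window",
    "scan_small_orfs",
    "detect_frameshift",
    "interval_codon_count",
    "map_region_coords",
]


class EmptyWindowError(ValueError):
    """No upstream sequence is available for the requested anchor."""


@dataclass
class OrfCandidate:
    """A small ORF; start/end are 1-based inclusive and include the stop codon
    when one terminates the ORF inside the scanned window."""

    genome_id: str
    start: int
    end: int
    strand: str
    frame: int
    peptide: str
    length_aa: int
    open_ended: bool = False

    @property
    def codon_count(self) -> int:
        return (self.end - self.start + 1) // 3


@dataclass
class FrameshiftCall:
    """A single-base edit that lengthens the local reading frame.

    ``position`` is the leftmost base of the homopolymer run in which the
    edit is placed (an indel inside a run of identical bases is
    indistinguishable from the same indel elsewhere in the run, so calls are
    collapsed to one per run spanning ``run_start``-``run_end``).
    """

    position: int
    edit: str  # "delete_1" or "insert_1:<base>"
    score: int  # nt gained by the edit (longest covering ORF after - before)
    fused_orf: Optional[OrfCandidate]
    run_start: int = 0
    run_end: int = 0


def interval_codon_count(start: int, end: int) -> int:
    """Codon count of a 1-based inclusive nucleotide interval."""
    n = end - start + 1
    if n <= 0 or n % 3:
        raise ValueError(f"interval {start}-{end} does not span whole codons")
    return n // 3


def upstream_window(
    anchor: GeneAnnotation,
    genome: GenomeRecord,
    window: int = DEFAULT_WINDOW,
    annotations: Sequence[GeneAnnotation] = (),
    truncate_at_genes: bool = True,
) -> tuple[int, int, str]:
    """Region of up to ``window`` nt immediately 5' of the anchor's start codon,
    on the anchor's strand, truncated at the genome edge and (optionally) at
    the nearest annotated same-strand gene."""
    if window <= 0:
        raise ValueError("window must be positive")
    anchor.validate(genome)
    others = [
        a
        for a in annotations
        if truncate_at_genes
        and a.gene_id != anchor.gene_id
        and a.genome_id == anchor.genome_id
        and a.strand == anchor.strand
    ]
    if anchor.strand == "+":
        start = max(1, anchor.start - window)
        end = anchor.start - 1
        for a in others:
            if a.end < anchor.start:
                start = max(start, a.end + 1)
    else:
        start = anchor.end + 1
        end = min(genome.length, anchor.end + window)
        for a in others:
            if a.start > anchor.end:
                end = min(end, a.start - 1)
    if start > end:
        raise EmptyWindowError(
            f"anchor {anchor.gene_id!r} has no upstream sequence in the genome"
        )
    return start, end, anchor.strand


def scan_small_orfs(
    region: str,
    min_aa: int = DEFAULT_MIN_AA,
    max_aa: int = DEFAULT_MAX_AA,
    starts: Sequence[str] = DEFAULT_STARTS,
    all_starts: bool = False,
    include_open_ended: bool = False,
    genome_id: str = "region",
    offset: int = 1,
    strand: str = "+",
    table: int = 11,
) -> list[OrfCandidate]:
    """Every ORF in the given (already strand-oriented) region, any frame.

    An ORF begins with a codon in ``starts``, ends at the first in-frame stop
    (included in its coordinates) or, if no stop occurs before the window
    edge, is flagged ``open_ended`` (excluded unless requested).  Overlapping
    ORFs sharing a stop keep only the longest unless ``all_starts``.  The
    peptide length (stop excluded) must fall in [min_aa, max_aa].
    ``offset`` is the 1-based coordinate of the region's first base, so
    coordinates can be reported in genome space.
    """
    if min_aa > max_aa:
        raise ValueError("min_aa must be <= max_aa")
    region = region.upper()
    n = len(region)
    if n < 3 * min_aa:
        logger.info("region of %d nt is shorter than 3*min_aa; no ORFs possible", n)
        return []
    start_set = {s.upper() for s in starts}
    stops = _stop_codons(table)
    out: list[OrfCandidate] = []

    def emit(pending: list[int], stop_end: int, frame: int, open_ended: bool) -> None:
        # length-filter first: an over-long ORF sharing the stop must not
        # shadow a shorter in-range one starting further downstream
        fitting = [
            _make_candidate(region, s, stop_end, frame, open_ended, genome_id, offset, strand, table)
            for s in pending
        ]
        fitting = [c for c in fitting if min_aa <= c.length_aa <= max_aa]
        out.extend(fitting if all_starts else fitting[:1])

    for frame in range(3):
        pending: list[int] = []  # 0-based start positions since last stop
        i = frame
        while i + 3 <= n:
            codon = region[i : i + 3]
            if codon in stops:
                emit(pending, i + 3, frame, False)
                pending = []
            elif codon in start_set:
                pending.append(i)
            i += 3
        if include_open_ended:
            emit(pending, i, frame, True)

    out.sort(key=lambda c: (c.start, c.end))
    return out


def _make_candidate(
    region: str,
    s: int,
    stop_end: int,
    frame: int,
    open_ended: bool,
    genome_id: str,
    offset: int,
    strand: str,
    table: int,
) -> OrfCandidate:
    coding_end = stop_end if open_ended else stop_end - 3
    peptide = translate(region[s:coding_end], table)
    return OrfCandidate(
        genome_id=genome_id,
        start=offset + s,
        end=offset + stop_end - 1,
        strand=strand,
        frame=frame,
        peptide=peptide,
        length_aa=len(peptide),
        open_ended=open_ended,
    )


def map_region_coords(
    rel_start: int, rel_end: int, region_start: int, region_end: int, strand: str
) -> tuple[int, int]:
    """Map 1-based coordinates inside a strand-oriented region back to
    forward-strand genome coordinates."""
    if strand == "+":
        return region_start + rel_start - 1, region_start + rel_end - 1
    return region_end - rel_end + 1, region_end - rel_start + 1


def _longest_orf_covering(
    region: str, pos: int, start_set: set[str], table: int
) -> tuple[int, Optional[tuple[int, int, int, bool]]]:
    """Length (nt) and (start, end0, frame, open_ended) of the longest ORF whose
    interval contains 0-based position ``pos``.  ORFs truncated by the window
    edge count, since windows cut through genes."""
    n = len(region)
    stops = _stop_codons(table)
    best_len, best = 0, None
    for frame in range(3):
        pending: Optional[int] = None
        i = frame
        while i + 3 <= n:
            codon = region[i : i + 3]
            if codon in stops:
                if pending is not None and pending <= pos < i + 3:
                    length = i + 3 - pending
                    if length > best_len:
                        best_len, best = length, (pending, i + 3, frame, False)
                pending = None
            elif pending is None and codon in start_set:
                pending = i
            i += 3
        if pending is not None and pending <= pos < i:
            length = i - pending
            if length > best_len:
                best_len, best = length, (pending, i, frame, True)
    return best_len, best


def _homopolymer_runs(region: str) -> list[tuple[int, int]]:
    runs = []
    i, n = 0, len(region)
    while i < n:
        j = i
        while j + 1 < n and region[j + 1] == region[i]:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def detect_frameshift(
    region: str,
    min_gain_aa: int = 20,
    include_insertions: bool = False,
    starts: Sequence[str] = DEFAULT_STARTS,
    table: int = 11,
    genome_id: str = "region",
    offset: int = 1,
) -> list[FrameshiftCall]:
    """Score every single-base deletion (and optionally insertion) by the
    nucleotide gain of the longest ORF covering the edited site.

    Edits within one homopolymer run are equivalent and collapse to a single
    call anchored at the run's leftmost base; more generally, score-tied
    calls that restore one and the same fused ORF (equal length, overlapping
    span) are merged into a single call spanning the whole ambiguous stretch,
    since frame arithmetic alone cannot localize the indel within it.  Calls
    gaining at least ``3 * min_gain_aa`` nt are returned, ranked by score
    (ties: leftmost).
    """
    region = region.upper()
    if len(region) < 60:
        raise ValueError("region too short for frameshift scanning (< 60 nt)")
    start_set = {s.upper() for s in starts}
    min_gain_nt = 3 * min_gain_aa
    calls: list[FrameshiftCall] = []

    def score_edit(edited: str, site: int) -> tuple[int, Optional[OrfCandidate]]:
        site = min(max(site, 0), len(edited) - 1)
        # the edited site corresponds to two original positions (the edit
        # shifts everything downstream by one base); take the better covering
        # ORF of the two so a mere coordinate shift never counts as gain
        before_len = max(
            _longest_orf_covering(region, min(site, len(region) - 1), start_set, table)[0],
            _longest_orf_covering(region, min(site + 1, len(region) - 1), start_set, table)[0],
        )
        after_len, info = _longest_orf_covering(edited, site, start_set, table)
        gain = after_len - before_len
        fused = None
        if info is not None:
            s, e0, frame, open_ended = info
            coding_end = e0 if open_ended else e0 - 3
            pep = translate(edited[s:coding_end], table)
            fused = OrfCandidate(
                genome_id=genome_id,
                start=offset + s,
                end=offset + e0 - 1,
                strand="+",
                frame=frame,
                peptide=pep,
                length_aa=len(pep),
                open_ended=open_ended,
            )
        return gain, fused

    for a, b in _homopolymer_runs(region):
        edited = region[:a] + region[a + 1 :]
        gain, fused = score_edit(edited, a)
        if gain >= min_gain_nt:
            calls.append(
                FrameshiftCall(
                    position=offset + a,
                    edit="delete_1",
                    score=gain,
                    fused_orf=fused,
                    run_start=offset + a,
                    run_end=offset + b,
                )
            )

    if include_insertions:
        for a, b in _homopolymer_runs(region):
            base = region[a]
            # inserting the run's own base anywhere in the run is one event;
            # inserting a different base is distinct per flank, but scanning
            # run boundaries covers every distinguishable outcome.
            for ins in "ACGT":
                edited = region[:a] + ins + region[a:]
                gain, fused = score_edit(edited, a)
                if gain >= min_gain_nt:
                    calls.append(
                        FrameshiftCall(
                            position=offset + a,
                            edit=f"insert_1:{ins}",
                            score=gain,
                            fused_orf=fused,
                            run_start=offset + a,
                            run_end=offset + (b if ins == base else a),
                        )
                    )

    calls = _merge_equivalent_calls(calls)
    calls.sort(key=lambda c: (-c.score, c.position))
    return calls


def _merge_equivalent_calls(calls: list[FrameshiftCall]) -> list[FrameshiftCall]:
    """Merge same-edit, score-tied calls that restore the same fused ORF.

    Fused-ORF coordinates live in edited space and may differ by one base
    between edit positions, so "the same ORF" means equal length and
    overlapping span.
    """
    merged: list[FrameshiftCall] = []
    for call in sorted(calls, key=lambda c: c.position):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.edit == call.edit
            and prev.score == call.score
            and prev.fused_orf is not None
            and call.fused_orf is not None
            and prev.fused_orf.length_aa == call.fused_orf.length_aa
            and prev.fused_orf.start <= call.fused_orf.end
            and call.fused_orf.start <= prev.fused_orf.end
        ):
            prev.run_end = max(prev.run_end, call.run_end)
        else:
            merged.append(call)
    return merged
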