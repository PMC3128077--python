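"""Genome/annotation I/O and translation primitives.

All genomic coordinates in this package are 1-based inclusive on the forward
strand, following the GFF3 convention; conversion to Python's 0-based
half-open slices happens only inside this module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_DNA = set("ACGTN")

__all__ = [
    "GenomeRecord",
    "GeneAnnotation",
    "ParseError",
    "ValidationError",
    "load_annotated_genome",
    "translate",
    "reverse_complement",
    "extract_subsequence",
    "write_candidates_tsv",
    "write_candidates_json",
]


class ParseError(ValueError):
    """A FASTA/GFF3 file could not be parsed."""


class ValidationError(ValueError):
    """An annotation violates its coordinate invariant."""


@dataclass
class GenomeRecord:
    """A genome (or contig) sequence over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_DNA
        if bad:
            raise ValidationError(
                f"genome {self.id!r} contains non-ACGTN symbols: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A gene feature with 1-based inclusive coordinates on genome_id."""

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    role: str = "other"  # {"anchor_subunit_II", "other"}

    def validate(self, genome: GenomeRecord) -> None:
        if not (1 <= self.start <= self.end <= genome.length):
            raise ValidationError(
                f"gene {self.gene_id!r}: interval {self.start}-{self.end} "
                f"outside genome {genome.id!r} of length {genome.length}"
            )
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


def load_annotated_genome(
    fasta_path: str | Path, gff_path: str | Path
) -> tuple[list[GenomeRecord], list[GeneAnnotation]]:
    """Read a multi-record FASTA and a GFF3 (gene features only).

    Every annotation is checked against its genome's bounds; GFF seqids that
    do not resolve to a FASTA record raise :class:`ValidationError`.  An empty
    GFF yields an empty annotation list with a logged warning.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    for p in (fasta_path, gff_path):
        if not p.exists():
            raise FileNotFoundError(p)

    genomes = [
        GenomeRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    if not genomes:
        raise ParseError(f"{fasta_path}: no FASTA records found")
    by_id = {g.id: g for g in genomes}

    feature_lines = [
        ln
        for ln in gff_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not feature_lines:
        logger.warning("%s: no gene features found", gff_path)
        return genomes, []

    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise ParseError(f"{gff_path}: malformed GFF3 ({exc})") from exc

    annotations: list[GeneAnnotation] = []
    for feat in db.features_of_type("gene"):
        if feat.seqid not in by_id:
            raise ValidationError(
                f"{gff_path}: seqid {feat.seqid!r} has no matching FASTA record"
            )
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        role = feat.attributes.get("role", ["other"])[0]
        ann = GeneAnnotation(
            gene_id=gene_id,
            genome_id=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand,
            role=role,
        )
        ann.validate(by_id[feat.seqid])
        annotations.append(ann)

    if not annotations:
        logger.warning("%s: no gene features found", gff_path)
    return genomes, annotations


@lru_cache(maxsize=8)
def _code(table: int) -> tuple[dict, frozenset]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    return dict(tbl.forward_table), frozenset(tbl.stop_codons)


def translate(dna: str, table: int = 11) -> str:
    """Translate codon by codon; stops render '*', N-containing codons 'X'.

    No internal-stop truncation is applied — the caller decides what a stop
    means.  The genetic code defaults to the bacterial/archaeal table 11
    (which matters only for the stop/start repertoire; initiator codons are
    translated literally, not forced to Met).
    """
    dna = dna.upper()
    bad = set(dna) - VALID_DNA
    if bad:
        raise ValueError(f"non-ACGTN symbols in DNA: {sorted(bad)}")
    if len(dna) % 3 != 0:
        raise ValueError(f"DNA length {len(dna)} not divisible by 3")
    fwd, stops = _code(table)
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in stops:
            out.append("*")
        else:
            out.append(fwd[codon])
    return "".join(out)


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def extract_subsequence(genome: GenomeRecord, start: int, end: int, strand: str) -> str:
    """Return the 1-based inclusive slice; '−' returns its reverse complement."""
    if not (1 <= start <= end <= genome.length):
        raise ValueError(
            f"interval {start}-{end} out of bounds for genome of length {genome.length}"
        )
    sub = genome.sequence[start - 1 : end]
    if strand == "+":
        return sub
    if strand == "-":
        return reverse_complement(sub)
    raise ValueError(f"bad strand {strand!r}")


def _candidate_records(candidates: Iterable) -> list[dict]:
    rows = []
    for c in candidates:
        rows.append(asdict(c) if hasattr(c, "__dataclass_fields__") else dict(c))
    return rows


def write_candidates_tsv(candidates: Sequence, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(_candidate_records(candidates)).to_csv(path, sep="\t", index=False)


def write_candidates_json(candidates: Sequence, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_candidate_records(candidates), indent=2, sort_keys=True) + "\n"
    )
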