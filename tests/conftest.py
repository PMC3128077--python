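import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20110630)


@pytest.fixture
def random_peptide(rng):
    def make(length: int) -> str:
        return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))

    return make


@pytest.fixture
def random_dna(rng):
    def make(length: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))

    return make


@pytest.fixture
def write_genome(tmp_path):
    """Write a (sequence, annotations) pair as FASTA + GFF3 files."""

    def make(sequence, annotations, genome_id="g1"):
        fasta = tmp_path / "genome.fasta"
        gff = tmp_path / "genome.gff3"
        fasta.write_text(f">{genome_id}\n{sequence}\n")
        lines = ["##gff-version 3"]
        for gene_id, start, end, strand in annotations:
            lines.append(
                f"{genome_id}\tx\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}"
            )
        gff.write_text("\n".join(lines) + "\n")
        return fasta, gff

    return make
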