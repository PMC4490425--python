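import pytest

from codonbias.seqio import OrfRecord
from codonbias.synth import GeneratorSpec, generate_corpus


def make_orf(
    n_codons: int,
    body_codon: str = "GAA",
    stop: str = "TAA",
    gene_id: str = "g",
    upstream: str = "",
    downstream: str = "",
) -> OrfRecord:
    """A structurally valid ORF of n_codons total (start + body + stop)."""
    return OrfRecord(
        id=gene_id,
        cds="ATG" + body_codon * (n_codons - 2) + stop,
        upstream_flank=upstream,
        downstream_flank=downstream,
    )


@pytest.fixture
def toy1():
    # one ORF: ATG GAA GAG GAA GAG TAA
    return OrfRecord(id="toy1", cds="ATGGAAGAGGAAGAGTAA")


@pytest.fixture
def toy2():
    # ATG GAG GAG GAG GAA TAA: Glu usage 3:1
    return OrfRecord(id="toy2", cds="ATGGAGGAGGAGGAATAA")


@pytest.fixture
def toy3():
    # body CTG CTG CTG
    return OrfRecord(id="toy3", cds="ATGCTGCTGCTGTAA")


@pytest.fixture(scope="session")
def uniform_corpus():
    """Null corpus: uniform amino acids and synonymous codons, ~430k codons."""
    records, _ = generate_corpus(GeneratorSpec(n_genes=2000, seed=11))
    return records
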