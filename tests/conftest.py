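import pytest

from gracilib import GeneModel, Genome, get_code

# Fig-style UTR stem-loop sequences used across hairpin tests: two from the
# repeat-gene UTRs and one from near a secretion-system gene.
UTR_3P = "ATTAAAAAAAGAGATTCGTATATCTCTTTTTTTAAT"
UTR_5P = "AAAAAACAACTCATTTTTATGAGTTGTTTTTT"
SECRETION = "AAAAAACACTGATAAAAATCAGTGTTTTTT"


@pytest.fixture(scope="session")
def code25():
    return get_code(25)


@pytest.fixture(scope="session")
def code11():
    return get_code(11)


@pytest.fixture
def toy_genome():
    """Two genes, one per strand, under code 25, with intergenic spacers.

    Layout (0-based):
      0-9    spacer  AATTAATTAA
      10-28  geneA + ATG CCA ACT GAT TGG TAA   (M P T D W *)
      28-37  spacer  CCGGCCGGC
      37-55  geneB − revcomp(ATG GAT ACA CCG TGA TAA) = (M D T P G *)
      55-64  spacer
    """
    gene_a_cds = "ATG" + "CCA" + "ACT" + "GAT" + "TGG" + "TAA"
    gene_b_cds = "ATG" + "GAT" + "ACA" + "CCG" + "TGA" + "TAA"
    from gracilib import reverse_complement

    seq = (
        "AATTAATTAA" + gene_a_cds + "CCGGCCGGC" + reverse_complement(gene_b_cds) + "ATATATATA"
    )
    genes = [
        GeneModel("geneA", 10, 28, "+", 25),
        GeneModel("geneB", 37, 55, "-", 25),
    ]
    return Genome(seq=seq, genes=genes, id="toy", circular=False)
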