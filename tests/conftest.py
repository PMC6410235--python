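import numpy as np
import pytest

from orfdecay.align import ScoringScheme
from orfdecay.gene_models import GeneModel, Genome
from orfdecay.simulate import generate_reference_gene


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def toy_gene():
    """3-exon reference gene (99+120+84 nt CDS) on a synthetic chromosome."""
    model, genome, table = generate_reference_gene(
        3, [99, 120, 84], [300, 350], seed=7, gene_id="toy", chrom="chr1"
    )
    return model, genome, table


def make_single_exon_gene(cds: str, chrom: str = "c", flank: int = 30) -> tuple[GeneModel, Genome]:
    """A one-exon gene embedded in random-free flanks (all 'A')."""
    seq = "A" * flank + cds + "A" * flank
    model = GeneModel(
        gene_id="g",
        chrom=chrom,
        strand="+",
        exons=((flank, flank + len(cds)),),
        cds_phases=(0,),
    )
    return model, Genome(sequences={chrom: seq})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
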