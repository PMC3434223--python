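import numpy as np
import pytest

from editcall import (
    ErrorModel,
    GeneModel,
    GenomeSequence,
    make_reference,
    plant_sites,
    simulate_reads,
)
from editcall.spectrum import SiteCounts


@pytest.fixture
def two_exon_plus():
    """Plus-strand model with exons [101-200] and [301-400]."""
    return GeneModel("tx1", "gene1", "chr1", "+", ((101, 200), (301, 400)))


@pytest.fixture
def single_exon_minus():
    """Minus-strand single-exon model spanning [101-200]."""
    return GeneModel("tx2", "gene2", "chr1", "-", ((101, 200),))


@pytest.fixture(scope="session")
def sim_truth():
    """Small deterministic simulation: 6 genes, 5 editing sites at 40%,
    2 het + 2 hom SNPs, Q30 errors."""
    genome, models = make_reference(seed=11)
    return plant_sites(
        genome, models, n_editing=5, levels=0.4, n_het_snps=2, n_hom_snps=2,
        seed=11, error_model=ErrorModel(phred=30),
    )


@pytest.fixture(scope="session")
def sim_reads(sim_truth):
    return simulate_reads(sim_truth, mean_coverage=100, read_len=50, seed=12)


def make_site(ref, filtered, raw=None, chrom="chr1", pos=100, n_plus=0, n_minus=0):
    filtered = np.asarray(filtered, dtype=np.int64)
    raw = filtered.copy() if raw is None else np.asarray(raw, dtype=np.int64)
    return SiteCounts(chrom, pos, ref, filtered, raw, n_plus, n_minus)
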