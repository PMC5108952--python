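import io

import numpy as np
import pytest

import betarank as br


@pytest.fixture
def zipf_ranked():
    """Exact Zipf sizes 100/r^0.5 at ranks 1..50 (no rounding)."""
    r = np.arange(1, 51, dtype=float)
    return br.RankedSizes(100.0 / r ** 0.5)


@pytest.fixture
def noisy_zipf_ranked():
    """Zipf sizes with mild log10 noise, seeded."""
    spec = br.SyntheticSpec(
        "zipf", {"log_c": 2.0, "a": 0.5}, n=200, noise_sd=0.05, seed=11, integerize=False
    )
    return br.rank_sizes(br.generate_rank_model_sizes(spec), min_size=1)


HGNC_TOY = """Approved symbol\tGene family ID\tStatus\tLocus type
ZNF1\tF1\tApproved\tgene with protein product
ZNF2\tF1\tApproved\tgene with protein product
ZNF3P\tF1\tApproved\tpseudogene
SLC1\tF2\tApproved\tgene with protein product
SLC2\tF2\tApproved\tgene with protein product
SLC3\tF2\tApproved\tgene with protein product
MIR1\tF2\tApproved\tRNA, micro
OLD1\tF2\tEntry Withdrawn\tgene with protein product
TRNA1\tF3\tApproved\tRNA, transfer
HOX1\tF3\tApproved\tgene with protein product
HOX2\tF3\tApproved\tgene with protein product
HOX1\tF1\tApproved\tgene with protein product
"""


@pytest.fixture
def hgnc_toy():
    """Small HGNC-style table exercising every curation filter.

    Without pseudo-genes: F1={ZNF1,ZNF2,HOX1}, F2={SLC1,SLC2,SLC3},
    F3={HOX1,HOX2}.  With pseudo-genes F1 gains ZNF3P.
    """
    return io.StringIO(HGNC_TOY)


ENSEMBL_TOY = """Gene stable ID\tEnsembl Family ID
ENSG01\tFAM1
ENSG02\tFAM1
ENSG02\tFAM1
ENSG03\tFAM2
ENSG04\tFAM3
ENSG05\tFAM3
ENSG06\tFAM3
"""


@pytest.fixture
def ensembl_toy():
    return io.StringIO(ENSEMBL_TOY)


@pytest.fixture
def hgnc_toy_text():
    return HGNC_TOY


@pytest.fixture
def ensembl_toy_text():
    return ENSEMBL_TOY
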