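import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from flcdna.simulate import SimConfig, make_reference_set, simulate_cdna_reads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)


NOISE_FREE = dict(
    sub_rate_by_region={"5UTR": 0.0, "CDS": 0.0, "3UTR": 0.0},
    indel_rate=0.0, p_vector_contam=0.0, p_vector_read=0.0, p_host_read=0.0,
    quality_decay=(40.0, 35.0),  # no quality trimming
)


@pytest.fixture(scope="session")
def noise_free_world():
    """Small simulation with zero divergence/contamination: reads are exact
    substrings of their reference transcripts."""
    cfg = SimConfig(seed=11, n_genes=25, n_reads=80, p_unknown=0.2,
                    n_novel_genomic=4, n_novel_free=4, n_otherdb=4, **NOISE_FREE)
    bundle = make_reference_set(cfg)
    reads, truth = simulate_cdna_reads(bundle, cfg)
    return cfg, bundle, reads, truth


@pytest.fixture(scope="session")
def diverged_world():
    """Default-rate simulation (divergence, indels, vector, novel reads)."""
    cfg = SimConfig(seed=7, n_genes=25, n_reads=80, p_te_exon=0.15)
    bundle = make_reference_set(cfg)
    reads, truth = simulate_cdna_reads(bundle, cfg)
    return cfg, bundle, reads, truth


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
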