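import numpy as np
import pytest

from panpav import pav_caller as pc
from panpav import synthetic_data as sd


@pytest.fixture(scope="session")
def small_truth():
    """4-line toy pangenome with SNPs, TEs and 5 novel contigs."""
    truth = sd.generate_pangenome(4, 60, 20, seed=7, n_novel_contigs=5,
                                  clade_fraction=0.5)
    for i, line in enumerate(truth.line_ids):
        sd.inject_snps(line, truth, 0.002, seed=100 + i, het_fraction=0.1)
    return truth


@pytest.fixture(scope="session")
def small_reads(small_truth):
    """Per-line alignment records simulated at 25x from the toy pangenome."""
    out = {}
    for i, line in enumerate(small_truth.line_ids):
        reads = sd.simulate_reads(line, small_truth, depth=25.0,
                                  seed=200 + i)
        out[line] = [r.to_alignment_record() for r in reads]
    return out


@pytest.fixture(scope="session")
def small_pav(small_truth, small_reads):
    seq_lengths = {c: len(s) for c, s in small_truth.reference.items()}
    return pc.call_pav_pipeline(small_reads, small_truth.gene_models,
                                seq_lengths, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
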