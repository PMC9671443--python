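import numpy as np
import pytest

import cistrans as ct


@pytest.fixture(scope="session")
def small_readsim():
    """A toy genome pair with indels and reads, shared across tests."""
    return ct.simulate_genome_pair(n_genes=8, snp_rate=0.01, indel_rate=0.003,
                                   seed=42, n_reads=600, read_length=100)


@pytest.fixture(scope="session")
def null_estimates():
    """Contrast estimates under the global null (no effects), 2000 genes."""
    truth = ct.make_truth(2000, seed=11, dispersion=0.1)
    design = ct.make_design("hemocyte", n_replicates=5, seed=12)
    matrix = ct.simulate_counts(truth, design, seed=13)
    return ct.fit_contrasts(matrix)


@pytest.fixture(scope="session")
def recovery_run():
    """Mixed-category simulation with |lfc|=2 effects and its estimates."""
    truth = ct.make_mixed_truth(600, seed=21, effect_size=2.0, dispersion=0.05)
    design = ct.make_design("hemocyte", n_replicates=5, seed=22)
    matrix = ct.simulate_counts(truth, design, seed=23)
    estimates = ct.fit_contrasts(matrix)
    return truth, estimates


def random_chain(rng, n_blocks=None):
    """A random well-formed alignment chain."""
    n_blocks = n_blocks or int(rng.integers(1, 8))
    blocks = []
    t = q = int(rng.integers(0, 50))
    for _ in range(n_blocks):
        size = int(rng.integers(5, 200))
        blocks.append((t, t + size, q, q + size))
        t += size + int(rng.integers(1, 30))
        q += size + int(rng.integers(1, 30))
    return ct.Chain("chrA", t + 100, "chrB", q + 100, np.array(blocks))
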