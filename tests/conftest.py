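import numpy as np
import pytest

from ssgwas.pedigree import Pedigree, renumber


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_pedigree(rng, n, p_founder=0.25):
    """Random valid pedigree of size n: each non-founder's parents drawn
    from earlier individuals."""
    sire = np.zeros(n + 1, dtype=np.int64)
    dam = np.zeros(n + 1, dtype=np.int64)
    for i in range(2, n + 1):
        if rng.random() > p_founder:
            sire[i] = rng.integers(1, i)
            dam[i] = rng.integers(1, i)
            if sire[i] == dam[i]:  # avoid selfing
                dam[i] = 0 if sire[i] == 1 else sire[i] - 1
    labels = np.empty(n + 1, dtype=object)
    labels[1:] = [f"a{i}" for i in range(1, n + 1)]
    return Pedigree(sire=sire, dam=dam, labels=labels)


@pytest.fixture
def trio():
    """A, B unrelated founders; C their offspring."""
    return renumber([("A", 0, 0), ("B", 0, 0), ("C", "A", "B")])


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset shared by integration-style tests."""
    from ssgwas import SimConfig, simulate_dataset

    cfg = SimConfig(n_founders=40, n_generations=3, n_per_generation=70,
                    n_snps=500, chromosomes={c: 30_000_000 for c in range(1, 5)},
                    n_qtl=1, qtl_variance_share=0.15, missing_rate=0.01, seed=7)
    return simulate_dataset(cfg, keep_haplotypes=True)
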