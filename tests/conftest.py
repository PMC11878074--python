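import numpy as np
import pytest

from stiffnet import AbundanceStudy, CooccurrenceNetwork, NetworkConfig
from stiffnet.study import COHORT_A, COHORT_B


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_study(abundance, n_a, n_b, taxa=None):
    """Small helper: study from a raw (taxa x samples) matrix."""
    abundance = np.asarray(abundance, dtype=float)
    n_taxa, n_samples = abundance.shape
    assert n_samples == n_a + n_b
    taxa = taxa or [f"t{i}" for i in range(n_taxa)]
    samples = [f"s{i}" for i in range(n_samples)]
    cohort = {s: (COHORT_A if i < n_a else COHORT_B)
              for i, s in enumerate(samples)}
    sums = abundance.sum(axis=0)
    return AbundanceStudy(taxa=taxa, samples=samples,
                          abundance=abundance / sums, cohort=cohort)


def random_signed_network(rng, n, edge_prob=0.5):
    """Random signed weighted network for oracle comparisons."""
    taxa = [f"t{i}" for i in range(n)]
    A = np.zeros((n, n), dtype=int)
    sign = np.zeros((n, n), dtype=int)
    W = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                A[i, j] = A[j, i] = 1
                s = 1 if rng.random() < 0.5 else -1
                sign[i, j] = sign[j, i] = s
                w = rng.uniform(0.3, 1.0)
                W[i, j] = W[j, i] = w
    return CooccurrenceNetwork(taxa=taxa, W=W, sign=sign, A=A)


@pytest.fixture
def small_study(rng):
    counts = rng.integers(1, 100, size=(6, 10)).astype(float)
    return make_study(counts, 5, 5)


@pytest.fixture
def default_cfg():
    return NetworkConfig()
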