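import numpy as np
import pytest

import longfs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(n=20, d=10, T=2, M=1, seed=0, **kw):
    """Small synthetic cohort for unit tests."""
    spec = longfs.SimSpec(n_per_class=n // 2, d=d, T=T, M=M,
                          n_informative=min(3, d), seed=seed, **kw)
    table, truth = longfs.generate(spec)
    return table, truth


@pytest.fixture
def tiny_cohort():
    """20 subjects, 10 features, T=2, M=1."""
    return make_cohort()


@pytest.fixture
def zero_laps():
    def _make(data):
        n = data.n_subjects
        return {
            (m, t): longfs.HypergraphLaplacian(np.zeros((n, n)))
            for m in range(data.n_modalities)
            for t in range(data.n_timepoints)
        }
    return _make


@pytest.fixture
def knn_laps():
    def _make(data, k=3):
        laps = {}
        for m in range(data.n_modalities):
            for t in range(data.n_timepoints):
                hg = longfs.build_knn_hypergraph(data.cell(m, t), k)
                laps[(m, t)] = longfs.laplacian(hg)
        return laps
    return _make
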