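import math

import numpy as np
import pytest

from emsfilter import ConditionPair, EpochedDataset


@pytest.fixture
def pair():
    return ConditionPair(0, 1)


@pytest.fixture
def hand_dataset():
    """2 channels, 1 sample, 4 trials: A = {(2,0),(0,2)}, B = {(-2,0),(0,-2)}."""
    data = np.array([[2.0, 0.0, -2.0, 0.0], [0.0, 2.0, 0.0, -2.0]]).reshape(2, 1, 4)
    return EpochedDataset(
        data=data, times=np.array([0.0]), labels=np.array([0, 0, 1, 1])
    )


@pytest.fixture
def small_random_dataset():
    rng = np.random.default_rng(7)
    m, n, p = 4, 6, 10
    data = rng.standard_normal((m, n, p))
    labels = np.array([0, 1] * (p // 2))
    times = np.arange(n) / 100.0
    return EpochedDataset(data=data, times=times, labels=labels)


def brute_force_loo_ems(data, labels, label_a=0, label_b=1):
    """Independent plain-Python oracle for LOO EMS with diff-of-means.

    Explicit per-fold, per-sample loops with scalar arithmetic; no shared
    code with the implementation under test.
    """
    m, n, p = data.shape
    surrogates = [[0.0] * n for _ in range(p)]
    filters = [[[0.0] * p for _ in range(n)] for _ in range(m)]
    for k in range(p):
        others = [t for t in range(p) if t != k]
        for j in range(n):
            idx_a = [t for t in others if labels[t] == label_a]
            idx_b = [t for t in others if labels[t] == label_b]
            d = []
            for i in range(m):
                ma = sum(data[i, j, t] for t in idx_a) / len(idx_a)
                mb = sum(data[i, j, t] for t in idx_b) / len(idx_b)
                d.append(ma - mb)
            nrm = math.sqrt(sum(v * v for v in d))
            if nrm == 0.0:
                w = [0.0] * m
            else:
                w = [v / nrm for v in d]
            for i in range(m):
                filters[i][j][k] = w[i]
            surrogates[k][j] = sum(w[i] * data[i, j, k] for i in range(m))
    return np.array(surrogates), np.array(filters)
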