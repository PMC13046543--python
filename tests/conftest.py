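import numpy as np
import pytest

from dynetfnc import synthdata as sd


@pytest.fixture(scope="session")
def small_dataset():
    """6 subjects, 192 TRs, 12^3 grid, 4 sources, 3 states, snr 5, mild jitter."""
    series, truth = sd.generate_dataset(
        n_subjects=6, T=192, grid_shape=(12, 12, 12), n_sources=4,
        k_states=3, snr=5.0, spatial_jitter=0.15, seed=7,
    )
    return series, truth


@pytest.fixture(scope="session")
def noiseless_dataset():
    series, truth = sd.generate_dataset(
        n_subjects=4, T=192, grid_shape=(12, 12, 12), n_sources=4,
        k_states=3, snr=np.inf, spatial_jitter=0.0, seed=11,
    )
    return series, truth


def match_components(est_maps: np.ndarray, true_maps: np.ndarray):
    """Hungarian-match rows of est_maps to true_maps by |r|; returns
    (perm, matched |r| values) with perm[i] = true index for est row i."""
    from scipy.optimize import linear_sum_assignment

    n, k = est_maps.shape[0], true_maps.shape[0]
    cc = np.zeros((n, k))
    for i in range(n):
        for j in range(k):
            cc[i, j] = abs(np.corrcoef(est_maps[i], true_maps[j])[0, 1])
    ri, ci = linear_sum_assignment(-cc)
    perm = dict(zip(ri.tolist(), ci.tolist()))
    return perm, cc[ri, ci]
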