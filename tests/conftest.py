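import numpy as np
import pandas as pd
import pytest

import microtopics as mt


def make_counts(array, samples=None, taxa=None) -> mt.CountMatrix:
    array = np.asarray(array, dtype=np.int64)
    samples = samples or [f"S{i}" for i in range(array.shape[0])]
    taxa = taxa or [f"T{j}" for j in range(array.shape[1])]
    return mt.CountMatrix(pd.DataFrame(array, index=samples, columns=taxa))


def make_model(phi, theta=None, alpha=None, beta=0.01, vocab=None, samples=None):
    """Build an LdaModel directly from probability tables (no fitting)."""
    phi = np.asarray(phi, dtype=float)
    K, V = phi.shape
    if theta is None:
        theta = np.full((2, K), 1.0 / K)
    theta = np.asarray(theta, dtype=float)
    return mt.LdaModel(
        K=K,
        alpha=np.full(K, 5.0 / K) if alpha is None else np.asarray(alpha, float),
        beta=beta,
        phi=phi,
        theta=theta,
        vocab=vocab or [f"T{j}" for j in range(V)],
        sample_ids=samples or [f"S{i}" for i in range(theta.shape[0])],
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """A small well-separated planted community shared across tests."""
    truth = mt.maize_like_truth(seed=11, n_samples=60, V=80, K=4,
                                effect_fold=3.0)
    return mt.simulate_corpus(truth, depth_range=(300, 600), seed=11)


@pytest.fixture(scope="session")
def fitted_model(planted_dataset):
    return mt.fit_lda(planted_dataset.counts, K=4, n_iter=200, seed=5)
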