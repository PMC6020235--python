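import numpy as np
import pandas as pd
import pytest

from acetyldiff import CountMatrix, SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_bundle():
    """One full synthetic study at the default configuration, shared read-only."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def null_count_matrix():
    """5000-feature two-group NB matrix with no planted effect (n=5 vs 4)."""
    rng = np.random.default_rng(20_240_101)
    n_feat, alpha = 5000, 0.05
    mu = np.exp(rng.uniform(np.log(20), np.log(500), size=n_feat))
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=9))
    mean = mu[:, None] * sf[None, :]
    n = 1.0 / alpha
    counts = rng.negative_binomial(n, n / (n + mean))
    samples = [f"case_{i}" for i in range(5)] + [f"control_{i}" for i in range(4)]
    groups = pd.Series({s: s.split("_")[0] for s in samples})
    return CountMatrix(
        pd.DataFrame(counts, index=[f"f{i}" for i in range(n_feat)], columns=samples),
        groups,
    )


def make_nb_matrix(rng, n_feat, lfc, mu_range=(100, 500), alpha=0.05, n_case=5, n_control=4):
    """NB count matrix with a planted log2 fold change in the case group.

    ``lfc`` may be a scalar (applied to every feature — note median-of-ratios
    normalization then absorbs it) or a per-feature vector.
    """
    lfc = np.broadcast_to(np.asarray(lfc, dtype=float), (n_feat,))
    mu = np.exp(rng.uniform(np.log(mu_range[0]), np.log(mu_range[1]), size=n_feat))
    n_samp = n_case + n_control
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samp))
    is_case = np.array([1.0] * n_case + [0.0] * n_control)
    mean = mu[:, None] * sf[None, :] * np.power(2.0, lfc[:, None] * is_case[None, :])
    n = 1.0 / alpha
    counts = rng.negative_binomial(n, n / (n + mean))
    samples = [f"case_{i}" for i in range(n_case)] + [f"control_{i}" for i in range(n_control)]
    groups = pd.Series({s: s.split("_")[0] for s in samples})
    return CountMatrix(
        pd.DataFrame(counts, index=[f"f{i}" for i in range(n_feat)], columns=samples),
        groups,
    )
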