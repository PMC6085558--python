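"""Shared fixtures.

The expensive objects -- the canonical planted dataset and the recovery
experiments on it -- are session-scoped so that module tests and the
acceptance suite measure the same computation once.
"""

from __future__ import annotations

import numpy as np
import pytest

from epsrank.data import SplitSpec
from epsrank.eps import eps_ranking
from epsrank.preprocess import estimate_size_factors, normalize, transform_features
from epsrank.rf import ForestConfig, rank_by_random_forest
from epsrank.synthetic import simulate_dataset

# the canonical planted fixture: 2,000 genes, 10 signal genes at
# |log2FC| = 2, 100 cases / 100 controls, NB dispersion 0.1
CANONICAL = dict(
    n_genes=2000,
    n_case=100,
    n_control=100,
    n_signal=10,
    effect_log2fc=2.0,
    dispersion=0.1,
    n_blocks=0,
    seed=11,
)


def recovered(ranking, truth, k: int = 20) -> int:
    return len(set(ranking.top(k)) & set(truth.signal_genes))


@pytest.fixture(scope="session")
def canonical_dataset():
    return simulate_dataset(**CANONICAL)


@pytest.fixture(scope="session")
def canonical_prepared(canonical_dataset):
    """Normalized matrix, all-training split, features, metadata, truth."""
    matrix, metadata, truth = canonical_dataset
    norm = normalize(matrix, estimate_size_factors(matrix))
    split = SplitSpec(training_ids=list(matrix.sample_ids), validation_ids=[], seed=0)
    features = transform_features(norm, split)
    return norm, split, features, metadata, truth


@pytest.fixture(scope="session")
def rf_recoveries(canonical_prepared):
    """Top-20 recovery of the 10 planted genes for 5 forest seeds."""
    _, split, features, metadata, truth = canonical_prepared
    out = []
    for seed in range(5):
        ranking, _ = rank_by_random_forest(
            features, metadata, split, ForestConfig.desk(seed=seed)
        )
        out.append((ranking, recovered(ranking, truth)))
    return out


@pytest.fixture(scope="session")
def eps_recoveries(canonical_prepared):
    """Top-20 recovery of the 10 planted genes for 3 EPS seeds."""
    _, split, features, metadata, truth = canonical_prepared
    out = []
    for seed in range(3):
        result = eps_ranking(features, metadata, split, seed=seed)
        out.append((result, recovered(result.ranking, truth)))
    return out


SMALL_SIM = dict(
    n_genes=250,
    n_case=120,
    n_control=40,
    n_signal=8,
    effect_log2fc=2.0,
    dispersion=0.1,
    seed=5,
    baseline_hazard=1e-3,
    censor_rate=0.3,
)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A complete three-method run on a small simulated cohort."""
    from epsrank.workflow import RunConfig, run_full_comparison

    out = tmp_path_factory.mktemp("run")
    config = RunConfig(simulate=dict(SMALL_SIM), epochs=40)
    run_full_comparison(config, out)
    return out, config


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian blobs: 50+50 samples, 30 features."""
    rng = np.random.default_rng(7)
    center = np.zeros(30)
    center[:10] = 3.0
    x_case = rng.standard_normal((50, 30)) + center
    x_control = rng.standard_normal((50, 30)) - center
    X = np.vstack([x_case, x_control])
    y = np.array([1] * 50 + [0] * 50)
    ids = [f"s{i:03d}" for i in range(100)]
    return X, y, ids


@pytest.fixture(scope="session")
def blob_vae(blob_data):
    from epsrank.vae import VAEArchitecture, train_vae

    X, y, ids = blob_data
    arch = VAEArchitecture((30, 32, 8, 32, 30))
    model, history = train_vae(X, arch, epochs=200, kl_weight=0.2, seed=0,
                               feature_names=[f"f{i:02d}" for i in range(30)])
    return model, history
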