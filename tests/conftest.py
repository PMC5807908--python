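import numpy as np
import pytest

import spikedecode as sd


@pytest.fixture(scope="session")
def tiny_config() -> sd.SessionConfig:
    return sd.SessionConfig(
        n_electrodes=4,
        n_units=10,
        movement_classes=3,
        trials_per_class=6,
        rest_trials=4,
        informative_fraction=0.4,
        effect_size=3.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_config) -> sd.Session:
    return sd.generate_session(tiny_config)


@pytest.fixture(scope="session")
def tiny_table(tiny_session) -> sd.FeatureTable:
    return sd.make_feature_table(tiny_session, mode="single-unit")


@pytest.fixture(scope="session")
def tiny_table_multi(tiny_session) -> sd.FeatureTable:
    return sd.make_feature_table(tiny_session, mode="multi-unit")


@pytest.fixture(scope="session")
def fast_svm() -> sd.SVMConfig:
    """Reduced grid/folds for runtime-bounded tests."""
    return sd.SVMConfig(
        sigma_grid=(0.1, 1.0, 10.0),
        c_grid=(1.0, 100.0),
        k_outer=4,
        k_inner=2,
        n_repeats=1,
        seed=0,
    )


def make_blob_table(
    n_classes: int = 3,
    n_per_class: int = 20,
    n_informative: int = 4,
    n_noise: int = 6,
    separation: float = 6.0,
    seed: int = 0,
) -> sd.FeatureTable:
    """Gaussian-blob FeatureTable: first columns carry class signal."""
    rng = np.random.default_rng(seed)
    n = n_classes * n_per_class
    y = np.repeat(np.arange(1, n_classes + 1), n_per_class)  # labels 1..k
    centers = rng.normal(0.0, separation, (n_classes, n_informative))
    X_info = centers[y - 1] + rng.normal(0.0, 1.0, (n, n_informative))
    X_noise = rng.normal(0.0, 1.0, (n, n_noise))
    X = np.hstack([X_info, X_noise])
    baseline = rng.normal(0.0, 1.0, X.shape)
    ids = [f"f{i}" for i in range(X.shape[1])]
    return sd.FeatureTable(
        X=X, baseline_X=baseline, y=y, feature_ids=ids, mode="single-unit"
    )
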