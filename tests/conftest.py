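import warnings

import numpy as np
import pytest

import hbpredict as hp
from hbpredict.cohort import FeatureMeta, FeatureTable, MissingnessTier


@pytest.fixture(autouse=True)
def _quiet_convergence():
    # perceptron / svm convergence chatter is irrelevant to the assertions
    warnings.filterwarnings("ignore", message=".*onvergence.*")
    warnings.filterwarnings("ignore", category=FutureWarning)
    yield


@pytest.fixture(scope="session")
def small_cohort():
    """Correlated 200x20 cohort with the default imbalanced class mix."""
    cfg = hp.GeneratorConfig(n_samples=200, n_features_per_tier=(6, 8, 6),
                             seed=11)
    return hp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def separated_cohort():
    """300x24 cohort with balanced, well-separated classes."""
    cfg = hp.GeneratorConfig(n_samples=300, n_features_per_tier=(8, 8, 8),
                             class_mix=(1 / 3, 1 / 3, 1 / 3), class_sep=4.0,
                             seed=7)
    return hp.generate_cohort(cfg)


def tiny_table(values, tiers, kinds=None, mask=None):
    """Hand-built FeatureTable for arithmetic oracles."""
    values = np.asarray(values, dtype=float)
    kinds = kinds or ["continuous"] * values.shape[1]
    meta = [FeatureMeta(f"f{i}", t, k)
            for i, (t, k) in enumerate(zip(tiers, kinds))]
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return FeatureTable(values, np.asarray(mask, dtype=bool), meta)


@pytest.fixture
def tiny_factory():
    return tiny_table


TIERS = MissingnessTier
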