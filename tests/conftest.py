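import numpy as np
import pytest

import pualpha as pa


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scar():
    """Small SCAR dataset for fast classifier-backed tests."""
    spec = pa.SyntheticSpec(n_pos=300, n_unl=900, frac_k=10, n_features=20,
                            n_informative=12, seed=7)
    return pa.make_scar(spec)


@pytest.fixture(scope="session")
def tiny_scar_scored(tiny_scar):
    return pa.cv_class1_probabilities(tiny_scar, folds=3, seed=7)


@pytest.fixture(scope="session")
def snar_reference_runs():
    """Clustered alpha estimation on the full five-subclass recipe.

    Ten seeded runs at 2,000 positives / 6,000 unlabeled with 20% hidden
    positives, shared by the cluster-structure unit tests and the
    end-to-end recovery checks.
    """
    runs = []
    for seed in range(10):
        data = pa.make_snar(pa.SyntheticSpec(
            n_pos=2_000, n_unl=6_000, frac_k=20, n_subclasses=5, seed=seed))
        runs.append((data, pa.estimate_alpha_snar(data, max_c=8, seed=seed)))
    return runs
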