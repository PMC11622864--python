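"""PU data model, out-of-fold scoring, and prior identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pualpha as pa


def toy_dataset(n_pos=20, n_unl=80):
    x = np.concatenate([np.full(n_pos, 1.0), np.full(n_unl, -1.0)])
    s = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_unl, dtype=int)])
    return pa.PUDataset(features=x.reshape(-1, 1), s=s)


class TestPUDataset:
    def test_labeled_must_be_true_positive(self):
        with pytest.raises(ValueError):
            pa.PUDataset(features=np.zeros((4, 1)), s=[1, 1, 0, 0],
                         y_true=[1, 0, 0, 0])

    def test_requires_both_label_groups(self):
        with pytest.raises(ValueError):
            pa.PUDataset(features=np.zeros((3, 1)), s=[1, 1, 1])

    def test_nonbinary_s_rejected(self):
        with pytest.raises(ValueError):
            pa.PUDataset(features=np.zeros((3, 1)), s=[0, 1, 2])


class TestCvProbabilities:
    def test_separable_data_ranks_positives_above_unlabeled(self):
        data = toy_dataset()
        scored = pa.cv_class1_probabilities(data, folds=5, seed=0)
        assert scored.p[data.s == 1].min() > scored.p[data.s == 0].max()

    def test_uninformative_features_give_labeled_fraction(self):
        data = pa.PUDataset(
            features=np.zeros((1_000, 2)),
            s=np.r_[np.ones(200, dtype=int), np.zeros(800, dtype=int)],
        )
        scored = pa.cv_class1_probabilities(data, folds=5, weight_positives=False, seed=0)
        assert scored.p.mean() == pytest.approx(0.2, abs=0.1)

    def test_output_contract_and_determinism(self, tiny_scar):
        a = pa.cv_class1_probabilities(tiny_scar, folds=3, seed=11)
        b = pa.cv_class1_probabilities(tiny_scar, folds=3, seed=11)
        assert a.p.shape == (tiny_scar.n_examples,)
        assert np.all((a.p >= 0) & (a.p <= 1))
        assert set(np.unique(a.fold_id)) == {0, 1, 2}
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.fold_id, b.fold_id)

    def test_out_of_fold_bookkeeping(self, tiny_scar):
        # every row belongs to exactly one scoring fold, and fold sizes are
        # near-balanced, so no model can have trained on a row it scored
        scored = pa.cv_class1_probabilities(tiny_scar, folds=4, seed=0)
        counts = np.bincount(scored.fold_id, minlength=4)
        assert counts.sum() == tiny_scar.n_examples
        assert counts.max() - counts.min() <= 1

    def test_too_few_positives_for_folds(self):
        data = toy_dataset(n_pos=3, n_unl=50)
        with pytest.raises(ValueError):
            pa.cv_class1_probabilities(data, folds=5)

    def test_nonfinite_features_rejected(self):
        data = toy_dataset()
        data.features[0, 0] = np.nan
        with pytest.raises(ValueError):
            pa.cv_class1_probabilities(data, folds=5)


class TestPriorIdentities:
    def test_hand_values(self):
        ps = pa.label_frequency_and_prior(2_000, 6_000, 0.1)
        assert ps.label_frequency == pytest.approx(2_000 / 2_600)
        assert ps.p_y1 == pytest.approx(0.325)
        assert pa.label_frequency_and_prior(2_000, 6_000, 0.0).label_frequency == 1.0
        lf = pa.label_frequency_and_prior(2_000, 6_000, 1.0)
        assert lf.label_frequency == pytest.approx(lf.p_s1) == pytest.approx(0.25)

    def test_alpha_bounds_enforced(self):
        with pytest.raises(ValueError):
            pa.label_frequency_and_prior(10, 10, 1.2)

    @settings(deadline=None, max_examples=100)
    @given(
        n_pos=st.integers(1, 10_000),
        n_unl=st.integers(1, 10_000),
        alpha=st.floats(0, 1),
    )
    def test_identity_label_frequency_times_prior(self, n_pos, n_unl, alpha):
        ps = pa.label_frequency_and_prior(n_pos, n_unl, alpha)
        assert ps.label_frequency * ps.p_y1 == pytest.approx(ps.p_s1, rel=1e-12)


class TestGainImportances:
    def test_informative_feature_outranks_noise(self, rng):
        n = 400
        s = np.r_[np.ones(100, dtype=int), np.zeros(300, dtype=int)]
        informative = np.where(s == 1, 2.0, -2.0) + rng.normal(0, 0.1, n)
        noise = rng.normal(size=n)
        data = pa.PUDataset(features=np.c_[informative, noise], s=s,
                            feature_names=["signal", "noise"])
        gains = pa.gain_importances(data, seed=0)
        assert gains["signal"] > gains["noise"]
        assert all(v >= 0 for v in gains.values())

    def test_constant_features_yield_zero_gains(self):
        data = pa.PUDataset(
            features=np.ones((100, 3)),
            s=np.r_[np.ones(30, dtype=int), np.zeros(70, dtype=int)],
        )
        gains = pa.gain_importances(data, seed=0)
        assert set(gains.values()) == {0.0}


class TestReadCsv:
    def test_roundtrip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({
            "a": [0.1, 0.2, 0.3, 0.4],
            "b": [1.0, 2.0, 3.0, 4.0],
            "s": [1, 1, 0, 0],
            "y_true": [1, 1, 0, 1],
        })
        path = tmp_path / "pu.csv"
        df.to_csv(path, index=False)
        data = pa.read_pu_csv(path, y_true_col="y_true")
        assert data.feature_names == ["a", "b"]
        assert data.n_pos == 2 and data.n_unl == 2
        assert np.array_equal(data.y_true, [1, 1, 0, 1])

    def test_invalid_label_column(self, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1, 2], "s": [0, 2]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            pa.read_pu_csv(path)
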