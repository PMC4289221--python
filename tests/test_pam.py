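import numpy as np
import pandas as pd
import pytest

from ersubgroups import (
    classify,
    cross_validate_threshold,
    select_subgroup_markers,
    train_shrunken_centroids,
)
from ersubgroups.pam import read_model, write_model


def _toy_informative(seed=0, n_noise=9, sep=4.0):
    """Two classes, one informative feature (means 0 vs `sep`, SD 1), the
    rest pure noise."""
    rng = np.random.default_rng(seed)
    n_per = 15
    info = np.concatenate([rng.normal(0, 1, n_per), rng.normal(sep, 1, n_per)])
    noise = rng.normal(0, 1, size=(n_noise, 2 * n_per))
    X = pd.DataFrame(np.vstack([info, noise]),
                     index=["g_info"] + [f"g_noise{i}" for i in range(n_noise)],
                     columns=[f"s{i}" for i in range(2 * n_per)])
    y = np.array(["low"] * n_per + ["high"] * n_per)
    return X, y


def _brute_force_d(X, y, delta):
    """d_ik from the definition, feature by feature and class by class."""
    classes = sorted(set(y))
    n = X.shape[1]
    overall = X.mean(axis=1)
    s2 = sum(((X.loc[:, y == c].sub(X.loc[:, y == c].mean(axis=1), axis=0)) ** 2)
             .sum(axis=1) for c in classes) / (n - len(classes))
    s = np.sqrt(s2)
    s0 = float(np.median(s))
    d = {}
    for c in classes:
        nk = int((y == c).sum())
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        dk = (X.loc[:, y == c].mean(axis=1) - overall) / (mk * (s + s0))
        d[c] = np.sign(dk) * np.maximum(0.0, np.abs(dk) - delta)
    return pd.DataFrame(d)


class TestTraining:
    def test_zero_shrinkage_reproduces_class_means(self):
        X, y = _toy_informative()
        model = train_shrunken_centroids(X, y, delta=0.0)
        for j, c in enumerate(model.classes):
            means = X.loc[:, y == c].mean(axis=1).to_numpy()
            assert np.max(np.abs(model.shrunken_centroids[:, j] - means)) < 1e-12

    def test_full_shrinkage_collapses_to_overall_centroid(self):
        X, y = _toy_informative()
        m0 = train_shrunken_centroids(X, y, delta=0.0)
        big = float(np.abs(m0.d).max()) + 1.0
        model = train_shrunken_centroids(X, y, delta=big)
        for j in range(len(model.classes)):
            assert np.allclose(model.shrunken_centroids[:, j],
                               model.overall_centroid)
        # classification degenerates to the prior argmax
        res = classify(model, X, threshold=0.5)
        prior_class = model.classes[int(np.argmax(model.priors))]
        # equal class sizes -> equal priors -> every posterior 1/2
        assert np.allclose(res.posteriors, 0.5)

    def test_shrunken_d_matches_brute_force_oracle(self):
        X, y = _toy_informative()
        # threshold between the noise and signal |d| ranges
        m0 = train_shrunken_centroids(X, y, delta=0.0)
        info_row = m0.feature_ids.index("g_info")
        noise_max = np.abs(np.delete(m0.d, info_row, axis=0)).max()
        info_min = np.abs(m0.d[info_row]).min()
        assert noise_max < info_min  # toy is constructed to separate
        delta = (noise_max + info_min) / 2.0
        model = train_shrunken_centroids(X, y, delta=delta)
        ref = _brute_force_d(X, y, delta)
        assert np.allclose(model.d_shrunk,
                           ref[model.classes].to_numpy(), atol=1e-12)
        active = model.active_features
        assert active[info_row] and active.sum() == 1

    def test_active_features_monotone_in_delta(self):
        X, y = _toy_informative(seed=3)
        counts = [train_shrunken_centroids(X, y, delta=d).active_features.sum()
                  for d in np.linspace(0, 6, 13)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_singleton_class_rejected(self):
        X, _ = _toy_informative()
        y = np.array(["a"] + ["b"] * (X.shape[1] - 1))
        with pytest.raises(ValueError, match="< 2 samples"):
            train_shrunken_centroids(X, y)

    def test_negative_delta_rejected(self):
        X, y = _toy_informative()
        with pytest.raises(ValueError, match="delta"):
            train_shrunken_centroids(X, y, delta=-0.1)


class TestMarkers:
    def _multiclass(self, seed=1, k=3, n_feat=30):
        rng = np.random.default_rng(seed)
        n_per = 10
        X = rng.normal(size=(n_feat, k * n_per))
        for g in range(k):
            X[g * 5:(g + 1) * 5, g * n_per:(g + 1) * n_per] += 4.0
        df = pd.DataFrame(X, index=[f"g{i:02d}" for i in range(n_feat)],
                          columns=[f"s{i}" for i in range(k * n_per)])
        y = np.repeat([f"c{j}" for j in range(k)], n_per)
        return df, y

    def test_disjoint_top_lists_give_full_panel(self):
        df, y = self._multiclass()
        model = train_shrunken_centroids(df, y)
        markers = select_subgroup_markers(model, n_per_class=5)
        assert len(markers) == 15
        assert set(markers.columns) == {"c0", "c1", "c2"}

    def test_overlapping_top_feature_shared_membership(self):
        df, y = self._multiclass()
        # make one feature dominate for every class
        df.loc["g00"] = 0.0
        for j, c in enumerate(["c0", "c1", "c2"]):
            df.loc["g00", np.asarray(y) == c] = j * 50.0
        model = train_shrunken_centroids(df, y)
        markers = select_subgroup_markers(model, n_per_class=1)
        assert len(markers) < 3
        assert markers.loc["g00"].sum() >= 2

    def test_oversized_request_rejected(self):
        df, y = self._multiclass()
        model = train_shrunken_centroids(df, y)
        with pytest.raises(ValueError, match="exceeds"):
            select_subgroup_markers(model, n_per_class=31)


class TestClassification:
    def test_sample_at_centroid_gets_maximal_posterior(self):
        df, y = TestMarkers()._multiclass(seed=5)
        model = train_shrunken_centroids(df, y)
        probe = pd.DataFrame(
            {"probe": model.shrunken_centroids[:, 1]}, index=model.feature_ids)
        res = classify(model, probe, threshold=0.5)
        assert res.predicted[0] == model.classes[1]
        assert res.posteriors[0, 1] == res.posteriors.max()

    def test_posteriors_sum_to_one(self, rng):
        df, y = TestMarkers()._multiclass(seed=6)
        model = train_shrunken_centroids(df, y)
        probes = pd.DataFrame(rng.normal(size=(df.shape[0], 1000)) * 10,
                              index=model.feature_ids)
        res = classify(model, probes)
        assert np.max(np.abs(res.posteriors.sum(axis=1) - 1.0)) < 1e-9

    def test_missing_features_dropped_symmetrically(self):
        df, y = TestMarkers()._multiclass(seed=7)
        model = train_shrunken_centroids(df, y)
        partial = df.drop(index=["g00", "g01"])  # 2/30 < 10%
        res = classify(model, partial)
        assert res.n_features_used == 28
        with pytest.raises(ValueError, match="missing"):
            classify(model, df.drop(index=[f"g{i:02d}" for i in range(4)]))

    def test_reduced_case_equals_nearest_centroid_oracle(self):
        from ersubgroups.benchmarks import nearest_centroid_oracle_agreement
        assert nearest_centroid_oracle_agreement(n_instances=20, seed=42) == 1.0

    def test_model_roundtrip_preserves_classification(self, tmp_path):
        df, y = TestMarkers()._multiclass(seed=8)
        model = train_shrunken_centroids(df, y, delta=0.5)
        path = tmp_path / "model.tsv"
        write_model(model, path)
        back = read_model(path)
        r1 = classify(model, df)
        r2 = classify(back, df)
        assert (r1.predicted == r2.predicted).all()
        assert np.max(np.abs(r1.posteriors - r2.posteriors)) < 1e-12


class TestCrossValidation:
    def test_separable_data_zero_error_at_small_delta(self):
        X, y = _toy_informative(sep=8.0)
        delta_star, table = cross_validate_threshold(
            X, y, delta_grid=[0.0, 0.5, 1.0], folds=3, seed=0)
        assert table.loc[table["delta"] == 0.0, "cv_error"].iloc[0] == 0.0
        assert delta_star >= 0.0

    def test_deterministic_under_seed(self):
        X, y = _toy_informative(seed=9)
        a = cross_validate_threshold(X, y, [0.0, 1.0, 2.0], folds=3, seed=5)
        b = cross_validate_threshold(X, y, [0.0, 1.0, 2.0], folds=3, seed=5)
        assert a[0] == b[0]
        assert a[1].equals(b[1])

    def test_chosen_delta_prunes_noise_keeps_signal(self):
        X, y = _toy_informative(sep=6.0)
        delta_star, _ = cross_validate_threshold(
            X, y, delta_grid=list(np.linspace(0, 4, 9)), folds=5, seed=1)
        model = train_shrunken_centroids(X, y, delta=delta_star)
        active = pd.Series(model.active_features, index=model.feature_ids)
        assert active["g_info"]
        assert not active.drop("g_info").any()

    def test_class_smaller_than_folds_rejected(self):
        X, y = _toy_informative()
        with pytest.raises(ValueError, match="folds"):
            cross_validate_threshold(X, y, [0.0], folds=20, seed=0)
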