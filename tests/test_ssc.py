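import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from msikit.dataset import MSIDataset, grid_pixels
from msikit.phantom import generate_centroid_phantom
from msikit.ssc import (
    SpatialShrunkenCentroids,
    cross_validate,
    ssc_fit_classifier,
    ssc_segment,
    ssc_top_features,
)

from conftest import make_dataset


def nearest_centroid_oracle(Xtr, ytr, X):
    """Independent diagonal-covariance nearest-centroid classifier.

    Pooled within-class sd per feature (plus the median offset) scales a
    squared distance to each class centroid; priors from class frequencies.
    """
    classes = np.unique(ytr)
    n, p = Xtr.shape
    cent = np.array([Xtr[ytr == c].mean(axis=0) for c in classes])
    ss = np.zeros(p)
    for c, cls in enumerate(classes):
        ss += ((Xtr[ytr == cls] - cent[c]) ** 2).sum(axis=0)
    sj = np.sqrt(ss / (n - len(classes)))
    s0 = np.median(sj)
    scale = (sj + s0) ** 2
    priors = np.array([(ytr == c).mean() for c in classes])
    priors = np.maximum(priors, 1.0 / (10 * n))
    priors /= priors.sum()
    scores = np.stack([
        (((X - cent[c]) ** 2) / scale).sum(axis=1) - 2 * np.log(priors[c])
        for c in range(len(classes))
    ], axis=1)
    return classes[np.argmin(scores, axis=1)]


def two_class_data(n=200, p=50, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X = rng.normal(0, 1, (n, p))
    X[y == "b", :5] += sep
    return X, y


class TestClassifier:
    def test_matches_nearest_centroid_oracle_exactly(self):
        X, y = two_class_data()
        est = SpatialShrunkenCentroids(r=0, s=0.0).fit(X, y)
        pred = est.predict(X)
        np.testing.assert_array_equal(pred, nearest_centroid_oracle(X, y, X))

    def test_shrunken_centroid_identity(self):
        # xbar'_kj = xbar_j + m_k (s_j + s0) d'_kj holds identically
        X, y = two_class_data(seed=1)
        for s in (0.0, 1.0, 5.0):
            est = SpatialShrunkenCentroids(r=0, s=s).fit(X, y)
            recon = est.overall_[None, :] + (
                est.m_k_[:, None] * (est.sj_ + est.s0_)[None, :]
                * est.shrunken_statistic_
            )
            np.testing.assert_allclose(est.shrunken_centroids_, recon,
                                       rtol=1e-10, atol=1e-12)
            # shrinkage never flips the sign
            assert np.all(
                est.shrunken_statistic_ * est.statistic_ >= -1e-12)

    def test_parameters_stored(self):
        X, y = two_class_data(seed=2)
        est = SpatialShrunkenCentroids(r=1, s=25.0)
        coords = grid_pixels(20, 10)
        est.fit(X, y)
        assert est.get_params()["r"] == 1
        assert est.get_params()["s"] == 25.0

    def test_single_class_labels_error(self):
        X, _ = two_class_data()
        with pytest.raises(ValueError, match=">= 2 classes"):
            SpatialShrunkenCentroids().fit(X, np.zeros(len(X)))

    def test_singleton_class_error(self):
        X, y = two_class_data()
        y = y.copy()
        y[:] = "a"
        y[0] = "lonely"
        with pytest.raises(ValueError, match="single pixel"):
            SpatialShrunkenCentroids().fit(X, y)

    def test_feature_mismatch_error(self):
        X, y = two_class_data()
        est = SpatialShrunkenCentroids(r=0).fit(X, y)
        with pytest.raises(ValueError, match="feature mismatch"):
            est.predict(X[:, :10])

    def test_uniform_data_predicts_majority_prior_class(self):
        X, y = two_class_data()
        y = np.array(["big"] * 150 + ["small"] * 50)
        est = SpatialShrunkenCentroids(r=0, s=1e6).fit(X, y)
        # total shrinkage: scores differ only through the priors
        pred = est.predict(np.zeros((10, X.shape[1])))
        assert set(pred) == {"big"}

    def test_probabilities_sum_to_one(self):
        X, y = two_class_data(seed=3)
        est = SpatialShrunkenCentroids(r=0, s=0.5).fit(X, y)
        _, proba = est.predict_proba_labels(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, rtol=1e-9)
        labels, _ = est.predict_proba_labels(X)
        np.testing.assert_array_equal(labels,
                                      est.classes_[np.argmax(proba, axis=1)])


def segmentation_phantom(seed=0, noise=0.25):
    """4 well-separated regions (3 segments + background), 16x32 grid.

    Each region gets one strongly enriched feature; two extra features carry
    weak, region-graded effects so the shrinkage path actually prunes.
    """
    peaks = {
        "A": {700.0: 10.0, 710.0: 1.0, 720.0: 1.0, 730.0: 1.0,
              740.0: 1.6, 750.0: 1.2},
        "B": {700.0: 1.0, 710.0: 10.0, 720.0: 1.0, 730.0: 1.0,
              740.0: 1.3, 750.0: 1.1},
        "C": {700.0: 1.0, 710.0: 1.0, 720.0: 10.0, 730.0: 1.0,
              740.0: 1.1, 750.0: 1.05},
        "bg": {700.0: 1.0, 710.0: 1.0, 720.0: 1.0, 730.0: 10.0,
               740.0: 1.0, 750.0: 1.0},
    }
    ds, lab = generate_centroid_phantom(
        128, peaks, noise_sd=noise, width=16, seed=seed)
    return ds, lab


class TestSegmentation:
    def test_recovers_four_regions_with_high_ari(self):
        ds, truth = segmentation_phantom()
        fit = ssc_segment(ds, r=1, k=10, s=0.0, seed=0)
        assert len(fit.classes_) == 4
        assert adjusted_rand_score(truth, fit.labels_) >= 0.95

    def test_total_shrinkage_collapses_to_one_class(self):
        ds, _ = segmentation_phantom(seed=1)
        fit = ssc_segment(ds, r=1, k=5, s=1e6, seed=0)
        assert fit.collapsed_
        assert len(fit.classes_) == 1

    def test_s_grid_returns_one_fit_per_value(self):
        ds, _ = segmentation_phantom(seed=2)
        fits = ssc_segment(ds, r=2, k=10, s=[0, 6, 12, 18, 24, 30], seed=0)
        assert len(fits) == 6

    def test_nonzero_feature_count_monotone_in_s(self):
        ds, _ = segmentation_phantom(seed=3)
        fits = ssc_segment(ds, r=1, k=10, s=[0.0, 6.0, 12.0], seed=0)
        counts = [int((f.shrunken_statistic_ != 0).sum()) for f in fits]
        assert counts[0] >= counts[1] >= counts[2]

    def test_assignment_objective_non_increasing_at_r0_s0(self):
        ds, _ = segmentation_phantom(seed=4)
        fit = ssc_segment(ds, r=0, k=4, s=0.0, seed=0)
        tr = fit.objective_trace_
        assert all(b <= a + 1e-6 for a, b in zip(tr, tr[1:]))

    def test_k_exceeding_pixels_errors(self):
        ds, _ = segmentation_phantom(seed=5)
        with pytest.raises(ValueError, match="exceeds pixel count"):
            ssc_segment(ds, k=10_000)

    def test_probabilities_invariant_to_feature_permutation(self):
        ds, _ = segmentation_phantom(seed=6)
        X = ds.intensity_matrix().T
        est1 = SpatialShrunkenCentroids(r=0, k=4, random_state=0).fit(X)
        perm = np.random.default_rng(0).permutation(X.shape[1])
        est2 = SpatialShrunkenCentroids(r=0, k=4, random_state=0).fit(X[:, perm])
        np.testing.assert_allclose(est1.probabilities_, est2.probabilities_,
                                   rtol=1e-8)


class TestTopFeatures:
    def test_enriched_feature_ranks_first(self):
        ds, truth = segmentation_phantom(seed=7)
        ds.pixels["seg"] = truth.to_numpy()
        model = ssc_fit_classifier(ds, "seg", r=0, s=0.0)
        # feature 700.0 is 10x enriched in class A
        top = ssc_top_features(model, "A", dataset=ds)
        assert top["mz"].iloc[0] == 700.0

    def test_total_shrinkage_gives_empty_list(self):
        X, y = two_class_data()
        est = SpatialShrunkenCentroids(r=0, s=1e6).fit(X, y)
        assert len(est.top_features("a")) == 0

    def test_unknown_class_errors(self):
        X, y = two_class_data()
        est = SpatialShrunkenCentroids(r=0).fit(X, y)
        with pytest.raises(ValueError, match="unknown class"):
            est.top_features("zzz")


class TestCrossValidation:
    def _core_dataset(self, n_cores=10, per_core=20, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        X = []
        for c in range(n_cores):
            cls = "tumor" if c % 2 == 0 else "stroma"
            mu = 8.0 if cls == "tumor" else 1.0
            for i in range(per_core):
                X.append(rng.normal(mu, 0.3, 6))
                rows.append((f"core{c}", cls))
        X = np.array(X).T
        n = X.shape[1]
        px = grid_pixels(per_core, n_cores)
        ds = MSIDataset(intensities=X, mz=np.arange(1.0, 7.0), pixels=px,
                        centroided=True)
        meta = pd.DataFrame(rows, columns=["core", "diagnosis"])
        ds.pixels["core"] = meta["core"].to_numpy()
        ds.pixels["diagnosis"] = meta["diagnosis"].to_numpy()
        return ds

    def test_separable_phantom_reaches_accuracy_one(self):
        ds = self._core_dataset()
        res = cross_validate(ds, "diagnosis", "core",
                             grid=[{"r": 0, "s": 0.0}], learner="ssc",
                             n_folds=5, seed=0)
        assert res.table["accuracy"].iloc[0] == 1.0

    def test_folds_partition_cores(self):
        ds = self._core_dataset()
        res = cross_validate(ds, "diagnosis", "core",
                             grid=[{"r": 0, "s": 0.0}], n_folds=5, seed=1)
        seen = [lvl for fold in res.folds for lvl in fold]
        assert sorted(seen) == sorted(ds.pixels["core"].unique())

    def test_accuracy_tie_selects_larger_s(self):
        ds = self._core_dataset()
        res = cross_validate(ds, "diagnosis", "core",
                             grid=[{"r": 0, "s": 0.0}, {"r": 0, "s": 5.0}],
                             n_folds=5, seed=0)
        assert res.best["s"] == 5.0

    def test_more_folds_than_levels_errors(self):
        ds = self._core_dataset(n_cores=3)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(ds, "diagnosis", "core",
                           grid=[{"r": 0, "s": 0.0}], n_folds=5)

    def test_per_fold_rebinning_hook_is_used(self):
        ds = self._core_dataset()
        calls = []

        def hook(train, test):
            calls.append((train.n_pixels, test.n_pixels))
            return train, test

        cross_validate(ds, "diagnosis", "core", grid=[{"r": 0, "s": 0.0}],
                       n_folds=5, rebin_hook=hook, seed=0)
        assert len(calls) == 5
        assert all(tr + te == ds.n_pixels for tr, te in calls)
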