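"""Spatial shrunken centroids (SSC) segmentation and classification.

The model is a nearest-shrunken-centroids classifier made spatially aware.
For classes k and features j, with class means xbar_kj, overall mean xbar_j,
pooled within-class standard deviation s_j, offset s0 = median_j(s_j) and
size factor m_k = sqrt(1/n_k - 1/n), the per-feature class statistic is

    d_kj = (xbar_kj - xbar_j) / (m_k (s_j + s0)),

soft-thresholded by the shrinkage parameter s,

    d'_kj = sign(d_kj) max(|d_kj| - s, 0),

and the shrunken centroid is xbar'_kj = xbar_j + m_k (s_j + s0) d'_kj.
Features whose statistic is fully shrunk contribute nothing beyond the
overall mean, so increasing s selects fewer, more discriminative features.

Spatial awareness enters through one mechanism: each pixel's spectrum is
replaced by its spatially weighted neighborhood average (Gaussian or
adaptive weights, radius r) before scoring

    score_ik = sum_j (xtilde_ij - xbar'_kj)^2 / (s_j + s0)^2 - 2 log pi_k,

both during the segmentation iterations and at prediction time.  With r=0
and s=0 this reduces to a diagonal-covariance nearest-centroid rule.

Estimators follow the sklearn conventions (``fit``/``predict``, trailing
underscore attributes); grid coordinates are passed alongside X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .dataset import MSIDataset
from .spatial import SpatialWeights, compute_spatial_weights

__all__ = [
    "SpatialShrunkenCentroids",
    "ssc_segment",
    "ssc_fit_classifier",
    "ssc_predict",
    "ssc_top_features",
    "cross_validate",
]


def _model_from_labels(X: np.ndarray, labels: np.ndarray, classes: np.ndarray,
                       s: float, prior_floor: float | None = None):
    """Shrunken-centroid statistics for given hard labels.

    X is (n_pixels, n_features).  Returns a dict of model arrays.
    """
    n, p = X.shape
    K = len(classes)
    overall = X.mean(axis=0)
    centroids = np.empty((K, p))
    n_k = np.empty(K, dtype=int)
    ss_within = np.zeros(p)
    for c, cls in enumerate(classes):
        mask = labels == cls
        n_k[c] = mask.sum()
        centroids[c] = X[mask].mean(axis=0)
        ss_within += ((X[mask] - centroids[c]) ** 2).sum(axis=0)
    dof = max(n - K, 1)
    s_j = np.sqrt(ss_within / dof)
    s0 = float(np.median(s_j))
    m_k = np.sqrt(np.maximum(1.0 / n_k - 1.0 / n, 0.0))
    m_k = np.maximum(m_k, np.finfo(float).eps)  # degenerate single-class guard
    denom = m_k[:, None] * (s_j + s0)[None, :]
    d = (centroids - overall[None, :]) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - s, 0.0)
    shrunken = overall[None, :] + denom * d_shrunk
    priors = n_k / n
    if prior_floor is None:
        prior_floor = 1.0 / (10.0 * n)
    priors = np.maximum(priors, prior_floor)
    priors = priors / priors.sum()
    return {
        "overall_": overall, "centroids_": centroids, "n_k_": n_k,
        "sj_": s_j, "s0_": s0, "m_k_": m_k, "statistic_": d,
        "shrunken_statistic_": d_shrunk, "shrunken_centroids_": shrunken,
        "priors_": priors,
    }


def _scores(Xs: np.ndarray, model: dict) -> np.ndarray:
    """Discriminant scores (n_pixels x K); lower is better."""
    scale = (model["sj_"] + model["s0_"]) ** 2
    cent = model["shrunken_centroids_"]
    sc = np.empty((Xs.shape[0], cent.shape[0]))
    for c in range(cent.shape[0]):
        sc[:, c] = (((Xs - cent[c]) ** 2) / scale).sum(axis=1)
    sc -= 2.0 * np.log(model["priors_"])[None, :]
    return sc


def _probabilities(scores: np.ndarray) -> np.ndarray:
    z = -0.5 * (scores - scores.min(axis=1, keepdims=True))
    p = np.exp(z)
    return p / p.sum(axis=1, keepdims=True)


class SpatialShrunkenCentroids(BaseEstimator):
    """Spatially aware nearest-shrunken-centroids model.

    Parameters
    ----------
    r : spatial neighborhood radius in grid units (0 disables smoothing).
    k : maximum class count for unsupervised segmentation.
    s : shrinkage (soft-threshold) parameter, >= 0.
    weights_method : "gaussian" or "adaptive" spatial weights.
    max_iter, tol : segmentation stopping rule — stop when fewer than
        ``tol`` (fraction) of the labels change, or after ``max_iter``.
    random_state : seed for the k-means initialization.

    Unsupervised use: ``fit(X, coords=...)`` — iterative segmentation,
    empty classes dropped.  Supervised use: ``fit(X, y, coords=...)`` —
    one pass of the model equations on the given labels.
    """

    def __init__(self, r=1, k=10, s=0.0, weights_method="gaussian",
                 max_iter=100, tol=1e-3, random_state=0):
        self.r = r
        self.k = k
        self.s = s
        self.weights_method = weights_method
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    def _weights(self, X: np.ndarray, coords: pd.DataFrame | None) -> SpatialWeights | None:
        if self.r == 0:
            return None
        if coords is None:
            raise ValueError("r > 0 requires pixel coordinates (coords=...)")
        spectra = X if self.weights_method == "adaptive" else None
        return compute_spatial_weights(coords, r=self.r,
                                       method=self.weights_method,
                                       spectra=spectra)

    @staticmethod
    def _smooth(X, weights: SpatialWeights | None):
        return X if weights is None else weights.smooth(X)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None, coords: pd.DataFrame | None = None,
            init_labels: np.ndarray | None = None):
        X = np.asarray(X, dtype=np.float64)
        n = X.shape[0]
        if y is not None:
            y = np.asarray(y)
            classes, counts = np.unique(y, return_counts=True)
            if len(classes) < 2:
                raise ValueError("classification requires >= 2 classes")
            if counts.min() < 2:
                small = classes[counts < 2].tolist()
                raise ValueError(
                    f"classes with a single pixel have undefined dispersion: {small}"
                )
            self.classes_ = classes
            model = _model_from_labels(X, y, classes, self.s)
            for key, val in model.items():
                setattr(self, key, val)
            self.n_iter_ = 0
            self.labels_ = y.copy()
            self.collapsed_ = bool(np.all(self.shrunken_statistic_ == 0))
            return self

        # unsupervised segmentation
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds pixel count {n}")
        weights = self._weights(X, coords)
        rng = np.random.default_rng(self.random_state)
        if init_labels is not None:
            labels = np.asarray(init_labels).copy()
        else:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            Z = (X - mu) / sd
            n_sub = max(self.k, int(np.ceil(0.1 * n)))
            sub = rng.choice(n, size=min(n_sub, n), replace=False)
            km = KMeans(n_clusters=self.k, n_init=1,
                        random_state=int(rng.integers(2 ** 31)))
            km.fit(Z[sub])
            labels = km.predict(Z)
        Xs = self._smooth(X, weights)
        self.objective_trace_ = []
        best_obj = np.inf
        best_labels = labels
        seen: set[bytes] = set()
        for it in range(1, self.max_iter + 1):
            classes = np.unique(labels)  # empty classes dropped here
            if len(classes) == 1:
                break
            key = labels.tobytes()
            cycling = key in seen
            seen.add(key)
            model = _model_from_labels(X, labels, classes, self.s)
            sc = _scores(Xs, model)
            new_labels = classes[np.argmin(sc, axis=1)]
            obj = float(sc.min(axis=1).sum())
            self.objective_trace_.append(obj)
            if obj < best_obj:
                best_obj = obj
                best_labels = labels
            if cycling:  # label cycle: settle on the best configuration seen
                labels = best_labels
                break
            changed = np.mean(new_labels != labels)
            labels = new_labels
            if changed < self.tol:
                break
        classes = np.unique(labels)
        model = _model_from_labels(X, labels, classes, self.s)
        for key, val in model.items():
            setattr(self, key, val)
        self.classes_ = classes
        self.labels_ = labels
        sc = _scores(Xs, model)
        self.probabilities_ = _probabilities(sc)
        self.n_iter_ = it
        self.collapsed_ = len(classes) == 1 or bool(
            np.all(self.shrunken_statistic_ == 0)
        )
        return self

    def predict(self, X, coords: pd.DataFrame | None = None,
                weights: SpatialWeights | None = None):
        labels, _ = self.predict_proba_labels(X, coords, weights)
        return labels

    def predict_proba_labels(self, X, coords=None, weights=None):
        """(labels, probabilities) with spatial smoothing on the query grid."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.shrunken_centroids_.shape[1]:
            raise ValueError(
                f"feature mismatch: model has {self.shrunken_centroids_.shape[1]} "
                f"features, data has {X.shape[1]}"
            )
        if weights is None:
            weights = self._weights(X, coords)
        Xs = self._smooth(X, weights)
        model = {k: getattr(self, k) for k in
                 ("sj_", "s0_", "shrunken_centroids_", "priors_")}
        sc = _scores(Xs, model)
        proba = _probabilities(sc)
        return self.classes_[np.argmin(sc, axis=1)], proba

    def top_features(self, cls, mz: np.ndarray | None = None,
                     n: int | None = None) -> pd.DataFrame:
        """Features with nonzero shrunken statistic for one class, ranked by |d'|."""
        matches = np.flatnonzero(self.classes_ == cls)
        if len(matches) == 0:
            raise ValueError(f"unknown class {cls!r}; have {self.classes_.tolist()}")
        c = int(matches[0])
        d = self.shrunken_statistic_[c]
        nz = np.flatnonzero(d != 0)
        order = nz[np.argsort(-np.abs(d[nz]))]
        if n is not None:
            order = order[:n]
        out = pd.DataFrame({
            "feature": order,
            "statistic": d[order],
            "centroid": self.shrunken_centroids_[c, order],
        })
        if mz is not None:
            out.insert(0, "mz", np.asarray(mz)[order])
        return out


# -- dataset-level wrappers -------------------------------------------------


def _xy(dataset: MSIDataset):
    return dataset.intensity_matrix().T, dataset.pixels


def ssc_segment(dataset: MSIDataset, r=2, k=10, s=0.0, weights_method="gaussian",
                max_iter=100, tol=1e-3, seed=0):
    """Unsupervised SSC segmentation; ``s`` may be a list (one fit per value).

    A list of shrinkage values is fitted as a warm-started path in ascending
    order: each fit initializes from the labels of the previous (smaller-s)
    fit, which keeps the segmentation stable along the path and makes the
    surviving-feature count shrink monotonically with s.
    """
    X, coords = _xy(dataset)
    svals = np.atleast_1d(np.asarray(s, dtype=float))
    order = np.argsort(svals)
    fits: list = [None] * len(svals)
    prev_labels = None
    for pos in order:
        est = SpatialShrunkenCentroids(
            r=r, k=k, s=float(svals[pos]), weights_method=weights_method,
            max_iter=max_iter, tol=tol, random_state=seed,
        ).fit(X, coords=coords, init_labels=prev_labels)
        fits[pos] = est
        prev_labels = est.labels_
    return fits if np.ndim(s) else fits[0]


def ssc_fit_classifier(dataset: MSIDataset, labels, r=1, s=0.0,
                       weights_method="gaussian"):
    """Single-pass supervised SSC model from per-pixel class labels."""
    X, _coords = _xy(dataset)
    y = np.asarray(dataset.pixels[labels] if isinstance(labels, str) else labels)
    est = SpatialShrunkenCentroids(r=r, s=s, weights_method=weights_method)
    return est.fit(X, y)


def ssc_predict(model: SpatialShrunkenCentroids, dataset: MSIDataset,
                weights: SpatialWeights | None = None):
    X, coords = _xy(dataset)
    return model.predict_proba_labels(X, coords=coords, weights=weights)


def ssc_top_features(model: SpatialShrunkenCentroids, cls, dataset=None, n=None):
    mz = dataset.features["mz"].to_numpy() if dataset is not None else None
    return model.top_features(cls, mz=mz, n=n)


# -- grouped cross-validation ----------------------------------------------


@dataclass
class CVResult:
    table: pd.DataFrame  # one row per parameter set, pooled accuracy
    best: dict
    folds: list  # list of lists of held-out fold-unit levels


def _partition_levels(levels, n_folds, seed):
    levels = list(levels)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(levels))
    folds = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(levels[idx])
    return folds


def cross_validate(dataset: MSIDataset, labels: str, fold_unit: str,
                   grid, learner: str = "ssc", n_folds: int = 5,
                   rebin_hook=None, seed: int = 0) -> CVResult:
    """Grouped cross-validation for SSC or PLS-DA classification.

    Folds partition the levels of ``fold_unit`` (e.g. tissue cores), never
    pixels, as evenly as possible (seeded).  With ``rebin_hook`` set, it is
    called as ``rebin_hook(train_ds, test_ds) -> (train_ds, test_ds)`` per
    fold so reference peaks are rebuilt from training spectra only.
    Accuracy is the pixel-level fraction correct pooled over held-out
    folds; ties go to the smaller model (larger s / fewer components).

    ``grid``: list of dicts — SSC: {"r": .., "s": ..}; PLS: {"ncomp": ..}.
    """
    px = dataset.pixels
    for col in (labels, fold_unit):
        if col not in px.columns:
            raise ValueError(f"unknown annotation column {col!r}")
    levels = pd.unique(px[fold_unit].dropna())
    if n_folds > len(levels):
        raise ValueError(
            f"{n_folds} folds but only {len(levels)} distinct {fold_unit!r} levels"
        )
    folds = _partition_levels(levels, n_folds, seed)
    from .dataset import subset_pixels

    rows = []
    for params in grid:
        correct = 0
        total = 0
        for held in folds:
            test_mask = px[fold_unit].isin(held).to_numpy()
            train_ds = subset_pixels(dataset, ~test_mask)
            test_ds = subset_pixels(dataset, test_mask)
            if rebin_hook is not None:
                train_ds, test_ds = rebin_hook(train_ds, test_ds)
            ytr = train_ds.pixels[labels].to_numpy()
            yte = test_ds.pixels[labels].to_numpy()
            if learner == "ssc":
                est = SpatialShrunkenCentroids(
                    r=params.get("r", 0), s=params.get("s", 0.0),
                ).fit(train_ds.intensity_matrix().T, ytr)
                pred = est.predict(test_ds.intensity_matrix().T,
                                   coords=test_ds.pixels)
            elif learner == "pls":
                from .stats import PLSDAClassifier

                est = PLSDAClassifier(n_components=params["ncomp"]).fit(
                    train_ds.intensity_matrix().T, ytr)
                pred = est.predict(test_ds.intensity_matrix().T)
            else:
                raise ValueError("learner must be 'ssc' or 'pls'")
            correct += int((pred == yte).sum())
            total += len(yte)
        rows.append({**params, "accuracy": correct / total})
    table = pd.DataFrame(rows)
    # ties to the smaller model: larger s (ssc) / fewer components (pls)
    if learner == "ssc":
        order = table.sort_values(["accuracy", "s"], ascending=[False, False])
    else:
        order = table.sort_values(["accuracy", "ncomp"], ascending=[False, True])
    best = order.iloc[0].to_dict()
    return CVResult(table=table, best=best, folds=folds)
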