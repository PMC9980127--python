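"""Co-localization, class comparison, PCA and PLS-DA.

Class comparison follows a group-then-test contract: per-feature intensities
are first averaged within each biological group (sample, ROI, tissue core),
and the Welch two-sample t-test is run across group means by condition, so
pixels are never treated as independent replicates.  P-values are adjusted
by Benjamini-Hochberg across features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SkPCA

from .dataset import MSIDataset, resolve_feature

__all__ = [
    "colocalize",
    "means_test",
    "welch_means_test",
    "PLSDAClassifier",
    "pls_fit",
    "pls_predict",
    "pca",
]


# -- co-localization --------------------------------------------------------


def colocalize(dataset: MSIDataset, mz: float, tol_ppm: float = 100.0,
               top_n: int | None = None) -> pd.DataFrame:
    """Rank features by Pearson correlation of their image with a query ion.

    The query feature itself is listed first with correlation exactly 1.
    """
    q = resolve_feature(dataset, mz, tol_ppm)
    X = dataset.intensity_matrix()
    qv = X[q]
    qc = qv - qv.mean()
    qn = np.sqrt((qc ** 2).sum())
    if qn == 0:
        raise ValueError("query feature has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ qc) / (norms * qn)
    corr[norms == 0] = np.nan
    corr[q] = 1.0  # corr(a, a) = 1 by definition
    out = pd.DataFrame({
        "feature": np.arange(len(corr)),
        "mz": dataset.features["mz"].to_numpy(),
        "correlation": corr,
    })
    out = out.sort_values("correlation", ascending=False, kind="mergesort")
    out = pd.concat([out[out["feature"] == q], out[out["feature"] != q]])
    out = out.reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n)
    return out


# -- class comparison -------------------------------------------------------


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return sps.false_discovery_control(p, method="bh")


def welch_means_test(group_means: np.ndarray, condition: np.ndarray) -> pd.DataFrame:
    """Welch t-test per feature across group means, BH-adjusted.

    ``group_means`` is (n_groups, n_features); ``condition`` the 2-level
    factor per group.
    """
    levels = pd.unique(pd.Series(condition))
    if len(levels) != 2:
        raise ValueError(f"condition must have exactly 2 levels, got {list(levels)}")
    a = group_means[np.asarray(condition) == levels[0]]
    b = group_means[np.asarray(condition) == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            "each condition level needs >= 2 groups (pixel-level "
            "pseudoreplication is refused)"
        )
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=False)
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    # zero-variance degeneracies: equal means -> no evidence (t=0, p=1)
    bad = ~np.isfinite(np.asarray(t))
    eq = bad & np.isclose(mean_a, mean_b)
    t = np.where(eq, 0.0, t)
    p = np.where(eq, 1.0, p)
    ne = bad & ~eq
    signed_inf = np.where(mean_a >= mean_b, np.inf, -np.inf)
    t = np.where(ne, signed_inf, t)
    p = np.where(ne, 0.0, p)
    return pd.DataFrame({
        f"mean_{levels[0]}": mean_a,
        f"mean_{levels[1]}": mean_b,
        "effect": mean_a - mean_b,
        "t": t,
        "p": p,
        "p_adj": _bh_adjust(np.clip(p, 0.0, 1.0)),
    })


def means_test(dataset: MSIDataset, group_unit: str, condition: str) -> pd.DataFrame:
    """Group-then-test class comparison over all features.

    Per level of ``group_unit`` (a sample/ROI annotation column), feature
    intensities are averaged over that group's pixels; groups are then
    compared across the two levels of ``condition`` by Welch's t-test.
    """
    px = dataset.pixels
    for col in (group_unit, condition):
        if col not in px.columns:
            raise ValueError(f"unknown annotation column {col!r}")
    sub = px[[group_unit, condition]].dropna()
    gmap = sub.drop_duplicates()
    if gmap[group_unit].duplicated().any():
        dup = gmap.loc[gmap[group_unit].duplicated(), group_unit].tolist()
        raise ValueError(f"groups spanning multiple condition levels: {dup}")
    X = dataset.intensity_matrix()
    means = []
    conds = []
    for (g, c) in gmap.itertuples(index=False):
        mask = (px[group_unit] == g).to_numpy()
        means.append(X[:, mask].mean(axis=1))
        conds.append(c)
    res = welch_means_test(np.asarray(means), np.asarray(conds))
    res.insert(0, "mz", dataset.features["mz"].to_numpy())
    return res


# -- PLS-DA -----------------------------------------------------------------


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """Partial least squares discriminant analysis.

    NIPALS PLS2 regression of mean-centered intensities onto the one-hot
    class matrix; prediction is the argmax of the regressed class scores
    (ties to the first class in training order).  Deterministic given the
    data.
    """

    def __init__(self, n_components=2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds the rank "
                f"({rank}) of the centered data"
            )
        self.classes_, codes = np.unique(y, return_inverse=True)
        Y = np.eye(len(self.classes_))[codes]
        self.pls_ = PLSRegression(n_components=self.n_components, scale=False)
        self.pls_.fit(X, Y)
        self.x_scores_ = self.pls_.x_scores_
        self.x_loadings_ = self.pls_.x_loadings_
        self.coef_ = self.pls_.coef_
        return self

    def decision_function(self, X):
        return self.pls_.predict(np.asarray(X, dtype=np.float64))

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def pls_fit(dataset: MSIDataset, labels, ncomp: int) -> PLSDAClassifier:
    y = np.asarray(dataset.pixels[labels] if isinstance(labels, str) else labels)
    return PLSDAClassifier(n_components=ncomp).fit(dataset.intensity_matrix().T, y)


def pls_predict(model: PLSDAClassifier, dataset: MSIDataset):
    X = dataset.intensity_matrix().T
    return model.predict(X), model.decision_function(X)


# -- PCA --------------------------------------------------------------------


def pca(dataset_or_matrix, ncomp: int):
    """Principal components of the mean-centered pixel x feature matrix.

    Returns (scores, loadings, explained_variance_ratio); loadings are
    orthonormal rows dotted as (n_features x ncomp) columns.
    """
    if isinstance(dataset_or_matrix, MSIDataset):
        X = dataset_or_matrix.intensity_matrix().T
    else:
        X = np.asarray(dataset_or_matrix, dtype=np.float64)
    if ncomp > min(X.shape):
        raise ValueError(f"ncomp={ncomp} exceeds min(n_pixels, n_features)")
    model = _SkPCA(n_components=ncomp, svd_solver="full")
    scores = model.fit_transform(X)
    return scores, model.components_.T, model.explained_variance_ratio_
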