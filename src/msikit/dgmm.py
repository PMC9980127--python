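"""Spatially aware Dirichlet Gaussian mixture model for single-ion
segmentation.

One ion image (a single feature's per-pixel intensities x_i) is segmented
into k intensity classes by EM on a Gaussian mixture whose mixing
proportions vary by pixel: after each E-step the responsibilities are
smoothed over the pixel's spatial neighborhood and regularized by a
Dirichlet pseudo-count a,

    pi_ik = (sum_{i' in N(i)} w_ii' gamma_i'k + a) / (1 + k a),

so neighboring pixels prefer the same segment.  Optional deterministic
annealing raises responsibilities to the power 1/T with T decreasing
geometrically from 2 to 1, flattening early assignments.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import MSIDataset, resolve_feature
from .spatial import SpatialWeights, compute_spatial_weights

__all__ = ["SpatialDGMM", "dgmm_segment"]


class SpatialDGMM(BaseEstimator):
    """Spatially smoothed univariate Gaussian mixture (EM).

    Parameters
    ----------
    k : number of mixture components (intensity classes).
    r : spatial radius for responsibility smoothing (0 = no smoothing).
    dirichlet_a : Dirichlet pseudo-count regularizing the spatial priors.
    annealing : deterministic annealing on/off (geometric schedule 2 -> 1,
        ratio 0.9).
    tol : relative log-likelihood change for convergence.
    random_state : seed for symmetry-breaking jitter of the initial means.

    Fitted attributes: ``means_``, ``sds_``, ``priors_`` (n x k),
    ``responsibilities_`` (n x k), ``labels_``, ``loglik_trace_``.
    """

    def __init__(self, k=2, r=1, dirichlet_a=1e-2, annealing=False,
                 max_iter=200, tol=1e-7, random_state=0):
        self.k = k
        self.r = r
        self.dirichlet_a = dirichlet_a
        self.annealing = annealing
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, x, coords=None, weights: SpatialWeights | None = None):
        x = np.asarray(x, dtype=np.float64).ravel()
        n = len(x)
        k = int(self.k)
        if k < 1:
            raise ValueError("k must be >= 1")
        if n < k:
            raise ValueError(f"need at least k={k} pixels, got {n}")
        a = float(self.dirichlet_a)
        if a <= 0:
            raise ValueError("dirichlet_a must be > 0")
        if weights is None and self.r > 0:
            if coords is None:
                raise ValueError("r > 0 requires pixel coordinates or weights")
            weights = compute_spatial_weights(coords, r=self.r, method="gaussian")

        rng = np.random.default_rng(self.random_state)
        rngspan = x.max() - x.min()
        sd_floor = max(1e-6 * rngspan, np.finfo(float).tiny)
        # means at the (2q-1)/(2k) quantiles, seeded jitter for symmetry breaking
        qs = (2 * np.arange(1, k + 1) - 1) / (2 * k)
        mu = np.quantile(x, qs) + rng.normal(0, 1e-6 * max(rngspan, 1.0), size=k)
        sd = np.full(k, max(x.std(), sd_floor))
        pi = np.full((n, k), 1.0 / k)

        self.sd_floored_ = False
        trace = []
        T = 2.0 if self.annealing else 1.0
        for _it in range(self.max_iter):
            # E-step
            log_phi = (
                -0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
                - np.log(sd[None, :]) - 0.5 * np.log(2 * np.pi)
            )
            logw = np.log(pi) + log_phi
            m = logw.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logw - m).sum(axis=1))
            gamma = np.exp(logw - lse[:, None])
            loglik = float(lse.sum())
            trace.append(loglik)
            if T > 1.0:
                gamma = gamma ** (1.0 / T)
                gamma = gamma / gamma.sum(axis=1, keepdims=True)
                T = max(T * 0.9, 1.0)
            # M-step
            nk = gamma.sum(axis=0)
            nk = np.maximum(nk, np.finfo(float).tiny)
            mu = (gamma * x[:, None]).sum(axis=0) / nk
            var = (gamma * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            new_sd = np.sqrt(var)
            if np.any(new_sd < sd_floor):
                self.sd_floored_ = True
            sd = np.maximum(new_sd, sd_floor)
            # spatial Dirichlet prior update
            sm = weights.smooth(gamma) if weights is not None else gamma
            pi = (sm + a) / (1.0 + k * a)
            pi = pi / pi.sum(axis=1, keepdims=True)
            if (len(trace) > 1 and T == 1.0
                    and abs(trace[-1] - trace[-2])
                    <= self.tol * max(abs(trace[-2]), 1.0)):
                break

        self.means_ = mu
        self.sds_ = sd
        self.priors_ = pi
        self.responsibilities_ = gamma
        self.labels_ = np.argmax(gamma, axis=1)
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        return self


def dgmm_segment(dataset: MSIDataset, mz: float, tol_ppm: float = 100.0,
                 r: int = 1, k: int = 2, annealing: bool = False,
                 dirichlet_a: float = 1e-2, max_iter: int = 200,
                 tol: float = 1e-7, seed: int = 0,
                 weights: SpatialWeights | None = None) -> SpatialDGMM:
    """Single-ion segmentation of the feature nearest the query m/z."""
    idx = resolve_feature(dataset, mz, tol_ppm)
    x = dataset.intensity_chunk(np.arange(dataset.n_pixels))[idx]
    est = SpatialDGMM(k=k, r=r, dirichlet_a=dirichlet_a, annealing=annealing,
                      max_iter=max_iter, tol=tol, random_state=seed)
    return est.fit(x, coords=dataset.pixels, weights=weights)
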