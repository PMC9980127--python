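"""Mass-axis correction.

Two complementary steps, usually applied in this order:

1. ``mz_align_to_mean`` removes per-spectrum mass jitter by warping each
   spectrum so its strongest local maxima line up with anchor peaks of the
   dataset mean spectrum (piecewise-linear warp, re-interpolated onto the
   shared axis).
2. ``recalibrate_internal`` removes the remaining systematic error by
   matching internal calibrants of known m/z in the mean spectrum, fitting
   a linear mass-error model e(m) = a + b*m, and correcting the shared axis.

Peak positions are refined by three-point parabolic apex interpolation so
residuals are not limited by the axis sampling step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ChunkPlan, MSIDataset, mean_spectrum
from .peaks import local_maxima

__all__ = [
    "CalibrationParams",
    "WarpFunction",
    "mz_align_to_mean",
    "recalibrate_internal",
    "refine_apex",
]


@dataclass(frozen=True)
class CalibrationParams:
    tol_ppm: float = 200.0
    calibrants: tuple = ()
    anchors: int = 20  # number of mean-spectrum maxima used for alignment
    window: int = 5  # local-maximum half-width in samples
    # anchor quality gate: local maxima below this fraction of the spectrum
    # maximum are noise bumps and are never used as warp control points
    min_rel_intensity: float = 0.05

    def __post_init__(self):
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        if list(self.calibrants) != sorted(self.calibrants):
            raise ValueError("calibrants must be sorted ascending")


def refine_apex(mz: np.ndarray, x: np.ndarray, i: int) -> float:
    """Sub-sample apex position by a parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(x) - 1:
        return float(mz[i])
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(mz[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    # local sample spacing (geometric axes are locally uniform)
    step = 0.5 * (mz[i + 1] - mz[i - 1])
    return float(mz[i] + delta * step)


@dataclass
class WarpFunction:
    """Piecewise-linear m/z correction through matched control points.

    Outside the control-point hull the correction tapers linearly to zero
    over a margin, so the warp stays continuous, strictly monotone, and is
    the identity far from the control points.
    """

    observed: np.ndarray  # control-point positions
    corrected: np.ndarray  # target positions
    margin: float = field(default=0.0)

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=np.float64)
        self.corrected = np.asarray(self.corrected, dtype=np.float64)
        order = np.argsort(self.observed)
        self.observed = self.observed[order]
        self.corrected = self.corrected[order]
        if self.margin <= 0:
            span = (self.observed[-1] - self.observed[0]) if len(self.observed) > 1 else 1.0
            self.margin = max(span, 1.0) * 0.05

    def __call__(self, m: np.ndarray) -> np.ndarray:
        obs = np.concatenate((
            [self.observed[0] - self.margin], self.observed,
            [self.observed[-1] + self.margin],
        ))
        corr = np.concatenate(([0.0], self.corrected - self.observed, [0.0]))
        out = np.asarray(m, np.float64) + np.interp(m, obs, corr, left=0.0, right=0.0)
        if np.any(np.diff(out) <= 0):
            raise ValueError("warp is not strictly monotone")
        return out


def _match_nearest(targets: np.ndarray, candidates: np.ndarray, tol_ppm: float):
    """For each target m/z, the nearest candidate within tol_ppm (or nan)."""
    out = np.full(len(targets), np.nan)
    if len(candidates) == 0:
        return out
    for k, t in enumerate(targets):
        d = np.abs(candidates - t)
        j = int(np.argmin(d))
        if d[j] <= t * tol_ppm * 1e-6:
            out[k] = candidates[j]
    return out


def mz_align_to_mean(dataset: MSIDataset, params: CalibrationParams,
                     plan: ChunkPlan = ChunkPlan(), chunk: int = 256):
    """Warp every spectrum so its peaks line up with the mean spectrum.

    Anchors are the ``params.anchors`` most intense local maxima of the mean
    spectrum.  Per spectrum, each anchor is matched to the nearest local
    maximum within ``tol_ppm``; matched pairs define a piecewise-linear
    warp of the sampling positions, and intensities are re-interpolated
    onto the shared axis.  Spectra with < 2 matches are left unwarped and
    flagged.  Returns (dataset, per-spectrum report DataFrame).
    """
    if dataset.mz is None:
        raise ValueError("alignment requires a shared m/z axis")
    mz = dataset.mz
    mspec = mean_spectrum(dataset, plan)
    lm = local_maxima(mspec, params.window)
    lm = lm[mspec[lm] >= params.min_rel_intensity * mspec.max()]
    if len(lm) == 0:
        raise ValueError("mean spectrum has no local maxima")
    top = lm[np.argsort(mspec[lm])[::-1][: params.anchors]]
    anchor_mz = np.sort(np.array([refine_apex(mz, mspec, i) for i in top]))

    n = dataset.n_pixels
    out = np.empty((len(mz), n))
    rows = []
    for c0 in range(0, n, chunk):
        c1 = min(c0 + chunk, n)
        block = dataset.intensity_chunk(np.arange(c0, c1))
        for j in range(c1 - c0):
            x = block[:, j]
            lmx = local_maxima(x, params.window)
            lmx = lmx[x[lmx] >= params.min_rel_intensity * x.max()]
            obs_mz = np.array([refine_apex(mz, x, i) for i in lmx])
            matched = _match_nearest(anchor_mz, obs_mz, params.tol_ppm)
            ok = ~np.isnan(matched)
            if ok.sum() < 2:
                out[:, c0 + j] = x
                rows.append((c0 + j, int(ok.sum()), 0.0, True))
                continue
            warp = WarpFunction(observed=matched[ok], corrected=anchor_mz[ok])
            warped_positions = warp(mz)
            out[:, c0 + j] = np.interp(mz, warped_positions, x)
            shift_ppm = np.median(
                (anchor_mz[ok] - matched[ok]) / anchor_mz[ok] * 1e6
            )
            rows.append((c0 + j, int(ok.sum()), float(shift_ppm), False))
    report = pd.DataFrame(rows, columns=["pixel", "n_matched", "shift_ppm", "flagged"])
    aligned = dataset._with(
        intensities=out,
        step=dataset.record("mz_align_to_mean", tol_ppm=params.tol_ppm,
                            anchors=params.anchors,
                            flagged=int(report["flagged"].sum())),
    )
    return aligned, report


def recalibrate_internal(dataset: MSIDataset, params: CalibrationParams,
                         plan: ChunkPlan = ChunkPlan()):
    """Correct the shared axis against internal calibrants of known m/z.

    Observed calibrant positions are apex-refined local maxima of the mean
    spectrum nearest each calibrant within ``tol_ppm``; a linear model of
    mass error versus m/z is fitted on the matched calibrants and the shared
    axis is corrected by subtracting the modeled error.  Requires >= 2
    matched calibrants.  Returns (dataset, report) where the report has one
    row per calibrant with before/after residuals in ppm.
    """
    if dataset.mz is None:
        raise ValueError("re-calibration requires a shared m/z axis")
    cal = np.asarray(params.calibrants, dtype=np.float64)
    if len(cal) < 2:
        raise ValueError("need at least 2 calibrants")
    mz = dataset.mz
    mspec = mean_spectrum(dataset, plan)
    lm = local_maxima(mspec, params.window)
    lm_mz = np.array([refine_apex(mz, mspec, i) for i in lm])
    observed = _match_nearest(cal, lm_mz, params.tol_ppm)
    ok = ~np.isnan(observed)
    if ok.sum() < 2:
        missed = cal[~ok].tolist()
        raise ValueError(
            f"only {int(ok.sum())} of {len(cal)} calibrants matched within "
            f"{params.tol_ppm} ppm; unmatched: {missed}"
        )
    err = observed[ok] - cal[ok]  # observed - true, in Da
    A = np.vstack([np.ones(ok.sum()), observed[ok]]).T
    coef, *_ = np.linalg.lstsq(A, err, rcond=None)
    new_mz = mz - (coef[0] + coef[1] * mz)
    if np.any(np.diff(new_mz) <= 0):
        raise ValueError("re-calibration produced a non-monotone axis")

    corrected = dataset._with(
        mz=new_mz,
        features=dataset.features.assign(mz=np.interp(
            dataset.features["mz"], mz, new_mz)),
        step=dataset.record("recalibrate_internal",
                            calibrants=cal.tolist(), tol_ppm=params.tol_ppm,
                            intercept=float(coef[0]), slope=float(coef[1])),
    )
    # residuals after: re-locate calibrant apexes on the corrected axis
    lm_after = np.array([refine_apex(new_mz, mspec, i) for i in lm])
    observed_after = _match_nearest(cal, lm_after, params.tol_ppm)
    report = pd.DataFrame({
        "calibrant_mz": cal,
        "matched": ok,
        "observed_mz": observed,
        "ppm_before": (observed - cal) / cal * 1e6,
        "ppm_after": (observed_after - cal) / cal * 1e6,
    })
    return corrected, report
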