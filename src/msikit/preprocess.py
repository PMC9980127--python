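"""Per-spectrum profile conditioning.

Gaussian smoothing, block-median baseline removal, total-ion-current (TIC)
normalization, and resampling of profile spectra onto a shared geometric
(constant-ppm) m/z axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ChunkPlan, MSIDataset, process_in_chunks
from .phantom import geometric_axis

__all__ = [
    "SmoothingParams",
    "BaselineParams",
    "smooth_gaussian",
    "remove_baseline_median",
    "normalize_tic",
    "resample_ppm_bins",
    "smooth_dataset",
    "remove_baseline_dataset",
]


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian kernel in samples: odd window (even inputs rounded up), sd > 0."""

    window: int = 9
    sd: float = 2.0

    def effective_window(self) -> int:
        w = max(int(self.window), 3)
        return w + 1 if w % 2 == 0 else w


@dataclass(frozen=True)
class BaselineParams:
    blocks: int = 750


def _gauss_kernel(window: int, sd: float) -> np.ndarray:
    if sd <= 0:
        raise ValueError("kernel sd must be > 0")
    half = window // 2
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def smooth_gaussian(spectrum: np.ndarray, params: SmoothingParams) -> np.ndarray:
    """Convolve with a truncated, renormalized Gaussian kernel.

    Edges are handled by renormalizing the part of the kernel that overlaps
    the signal, so no padding values are invented and a constant spectrum is
    left exactly unchanged.
    """
    w = params.effective_window()
    k = _gauss_kernel(w, params.sd)
    x = np.asarray(spectrum, dtype=np.float64)
    num = np.convolve(x, k, mode="same")
    norm = np.convolve(np.ones_like(x), k, mode="same")
    return num / norm


def remove_baseline_median(spectrum: np.ndarray, params: BaselineParams) -> np.ndarray:
    """Subtract a baseline of per-block medians, clamped at zero.

    The spectrum index axis is split into ``blocks`` equal-width blocks; the
    baseline is the per-block medians linearly interpolated at block centers,
    with constant extrapolation beyond the outermost centers.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    n = len(x)
    b = int(params.blocks)
    if b < 1 or b > n:
        raise ValueError(f"blocks must be in [1, {n}], got {b}")
    edges = np.linspace(0, n, b + 1).astype(int)
    centers = (edges[:-1] + edges[1:] - 1) / 2.0
    meds = np.array([np.median(x[lo:hi]) for lo, hi in zip(edges[:-1], edges[1:])])
    baseline = np.interp(np.arange(n), centers, meds)
    return np.maximum(x - baseline, 0.0)


def _apply_per_spectrum(dataset: MSIDataset, fn, step_name, chunk: int = 256, **params):
    """Materialized per-spectrum map over a continuous dataset (chunk-wise)."""
    if not dataset.is_continuous:
        raise ValueError(f"{step_name} requires a shared m/z axis")
    n = dataset.n_pixels
    out = np.empty((dataset.n_features, n))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        block = dataset.intensity_chunk(np.arange(lo, hi))
        for j in range(hi - lo):
            out[:, lo + j] = fn(block[:, j])
    return dataset._with(
        intensities=out, step=dataset.record(step_name, **params)
    )


def smooth_dataset(dataset: MSIDataset, params: SmoothingParams) -> MSIDataset:
    eff = params.effective_window()
    return _apply_per_spectrum(
        dataset, lambda s: smooth_gaussian(s, params), "smooth_gaussian",
        window=params.window, effective_window=eff, sd=params.sd,
    )


def remove_baseline_dataset(dataset: MSIDataset, params: BaselineParams) -> MSIDataset:
    return _apply_per_spectrum(
        dataset, lambda s: remove_baseline_median(s, params),
        "remove_baseline_median", blocks=params.blocks,
    )


def normalize_tic(dataset: MSIDataset, plan: ChunkPlan = ChunkPlan()) -> MSIDataset:
    """Scale each spectrum so its intensity sum equals the pre-scaling mean TIC.

    All-zero spectra are left unchanged and flagged in a boolean pixel
    annotation column ``tic_zero``.
    """
    tics = np.empty(dataset.n_pixels)
    for lo in range(0, dataset.n_pixels, plan.chunk_size or dataset.n_pixels):
        hi = min(lo + (plan.chunk_size or dataset.n_pixels), dataset.n_pixels)
        tics[lo:hi] = dataset.intensity_chunk(np.arange(lo, hi)).sum(axis=0)
    mean_tic = process_in_chunks(dataset, lambda s: s.sum(), lambda a, b: a + b,
                                 plan) / dataset.n_pixels
    zero = tics == 0
    scale = np.ones_like(tics)
    scale[~zero] = mean_tic / tics[~zero]
    from .dataset import _ScaledColumnStore

    pixels = dataset.pixels.copy()
    pixels["tic_zero"] = zero
    out = dataset._with(
        intensities=_ScaledColumnStore(dataset._store, scale),
        pixels=pixels,
        step=dataset.record("normalize_tic", mean_tic=float(mean_tic),
                            n_zero=int(zero.sum())),
    )
    return out


def resample_ppm_bins(dataset: MSIDataset, ppm: float, agg: str = "mean") -> MSIDataset:
    """Resample spectra onto a shared geometric axis of constant-ppm bins.

    Bin edges follow m_{i+1} = m_i (1 + ppm*1e-6) from the global minimum to
    the global maximum observed m/z; a spectrum's value in bin i is the mean
    (or sum, for centroided input) of its samples in [m_i, m_{i+1}), zero if
    none fall there.  The result is continuous-mode.
    """
    if ppm <= 0:
        raise ValueError("ppm must be > 0")
    if dataset.n_pixels == 0:
        raise ValueError("cannot resample an empty dataset")
    lo = np.inf
    hi = -np.inf
    for i in range(dataset.n_pixels):
        m, _ = dataset.spectrum(i)
        if len(m):
            lo = min(lo, m[0])
            hi = max(hi, m[-1])
    if not np.isfinite(lo):
        raise ValueError("dataset has no m/z samples")
    edges = geometric_axis(lo, hi, ppm)
    nb = len(edges) - 1
    centers = edges[:-1]  # axis points are the bin left edges
    X = np.zeros((nb, dataset.n_pixels))
    for i in range(dataset.n_pixels):
        m, x = dataset.spectrum(i)
        idx = np.searchsorted(edges, m, side="right") - 1
        ok = (idx >= 0) & (idx < nb)
        sums = np.bincount(idx[ok], weights=x[ok], minlength=nb)
        if agg == "mean":
            counts = np.bincount(idx[ok], minlength=nb)
            nz = counts > 0
            sums[nz] = sums[nz] / counts[nz]
        X[:, i] = sums
    pixels = dataset.pixels
    out = MSIDataset(
        intensities=X, mz=centers, pixels=pixels,
        features=pd.DataFrame({"mz": centers}),
        centroided=dataset.centroided,
        provenance=list(dataset.provenance),
    )
    out.provenance.append(out.record("resample_ppm_bins", ppm=ppm, agg=agg,
                                     n_bins=nb))
    return out
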