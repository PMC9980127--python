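"""Noise estimation, peak detection, reference peak lists, and peak
integration onto a centroided dataset (peak binning).

Noise is estimated block-wise and interpolated over the full axis; a sample
is a peak when it is the strict maximum of its +/-window neighborhood (ties
resolved to the leftmost index) and exceeds snr times the local noise.
Reference peaks are detected on the mean spectrum; per-spectrum detection
frequency and mean intensity support frequency filtering.  Integration uses
the trapezoidal rule over a +/-ppm window around each reference m/z,
truncated at midpoints between adjacent references to avoid double counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ChunkPlan, MSIDataset, mean_spectrum, process_in_chunks

__all__ = [
    "PeakDetectParams",
    "ReferencePeaks",
    "estimate_noise",
    "detect_peaks",
    "local_maxima",
    "build_reference",
    "filter_reference",
    "integrate_peak_areas",
]


@dataclass(frozen=True)
class PeakDetectParams:
    method: str = "mad"  # "mad" or "simple"
    snr: float = 6.0
    window: int = 5  # local-maximum half-width in samples
    blocks: int = 100  # noise-estimation block count

    def __post_init__(self):
        if self.method not in ("mad", "simple"):
            raise ValueError("method must be 'mad' or 'simple'")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.window < 1 or self.blocks < 1:
            raise ValueError("window and blocks must be >= 1")


@dataclass
class ReferencePeaks:
    """Reference peak list with dataset-level statistics per peak."""

    mz: np.ndarray  # ascending
    freq: np.ndarray  # detection frequency in [0, 1]
    mean_intensity: np.ndarray

    def __len__(self):
        return len(self.mz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mz": self.mz, "freq": self.freq, "mean_intensity": self.mean_intensity}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferencePeaks":
        return cls(df["mz"].to_numpy(float), df["freq"].to_numpy(float),
                   df["mean_intensity"].to_numpy(float))


def estimate_noise(spectrum: np.ndarray, method: str = "mad",
                   blocks: int = 100) -> np.ndarray:
    """Per-sample noise level from block-wise robust scale estimates.

    ``mad``: 1.4826 * median(|x - median(x)|) per block (Gaussian-consistent
    median absolute deviation).  ``simple``: mean(|x - mean(x)|) per block.
    Block values are linearly interpolated at block centers (constant
    extrapolation at the ends) and floored at machine epsilon.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    n = len(x)
    b = min(int(blocks), n)
    if b < 1:
        raise ValueError("blocks must be >= 1")
    edges = np.linspace(0, n, b + 1).astype(int)
    centers = (edges[:-1] + edges[1:] - 1) / 2.0
    vals = np.empty(b)
    for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        blk = x[lo:hi]
        if method == "mad":
            vals[k] = 1.4826 * np.median(np.abs(blk - np.median(blk)))
        elif method == "simple":
            vals[k] = np.mean(np.abs(blk - np.mean(blk)))
        else:
            raise ValueError("method must be 'mad' or 'simple'")
    noise = np.interp(np.arange(n), centers, vals)
    return np.maximum(noise, np.finfo(np.float64).eps)


def local_maxima(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Indices i with x_i > x_j for all j in [i-window, i+window], ties leftmost.

    A plateau maximum reports its leftmost sample: x_i must strictly exceed
    every earlier neighbor and be >= every later neighbor in the window.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n == 0:
        return np.empty(0, dtype=np.intp)
    w = int(window)
    pad = np.full(w, -np.inf)
    xp = np.concatenate([pad, x, pad])
    win = sliding_window_view(xp, 2 * w + 1)  # win[i] = x[i-w : i+w+1]
    wmax = win.max(axis=1)
    # max over the finite part only, for the flat-window exclusion
    wmin = np.where(np.isfinite(win), win, np.inf).min(axis=1)
    left_max = sliding_window_view(np.concatenate([pad, x]), w)[:n].max(axis=1)
    cand = (x >= wmax) & (x > left_max) & (wmax > wmin)
    return np.flatnonzero(cand).astype(np.intp)


def detect_peaks(spectrum: np.ndarray, params: PeakDetectParams,
                 noise: np.ndarray | None = None,
                 mz: np.ndarray | None = None) -> pd.DataFrame:
    """Detect peaks on one spectrum: local maxima above snr * noise.

    Returns a DataFrame with columns index, mz (if an axis is given),
    intensity, snr.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    if noise is None:
        noise = estimate_noise(x, params.method, params.blocks)
    cand = local_maxima(x, params.window)
    keep = cand[x[cand] >= params.snr * noise[cand]]
    out = pd.DataFrame({
        "index": keep,
        "intensity": x[keep],
        "snr": x[keep] / noise[keep],
    })
    if mz is not None:
        out.insert(1, "mz", np.asarray(mz, dtype=np.float64)[keep])
    return out


def build_reference(dataset: MSIDataset, params: PeakDetectParams,
                    tol_ppm: float = 15.0,
                    plan: ChunkPlan = ChunkPlan()) -> ReferencePeaks:
    """Detect peaks on the mean spectrum and attach dataset statistics.

    Detection frequency of a reference peak is the fraction of spectra with
    a local maximum within ``tol_ppm``; mean intensity is the pixel mean of
    the maximum intensity inside the +/-tol_ppm window.
    """
    mspec = mean_spectrum(dataset, plan)
    pk = detect_peaks(mspec, params, mz=dataset.mz)
    if len(pk) == 0:
        raise ValueError(
            "no peaks detected on the mean spectrum; try a lower snr threshold"
        )
    ref_mz = pk["mz"].to_numpy()
    mz = dataset.mz
    half = ref_mz * tol_ppm * 1e-6
    los = np.searchsorted(mz, ref_mz - half, side="left")
    his = np.searchsorted(mz, ref_mz + half, side="right")

    def per_spectrum(x):
        lm = local_maxima(x, params.window)
        lm_mz = mz[lm] if len(lm) else np.empty(0)
        hits = np.zeros(len(ref_mz))
        peak_int = np.zeros(len(ref_mz))
        for k in range(len(ref_mz)):
            if len(lm_mz):
                d = np.abs(lm_mz - ref_mz[k])
                hits[k] = 1.0 if d.min() <= half[k] else 0.0
            if his[k] > los[k]:
                peak_int[k] = x[los[k]:his[k]].max()
        return np.concatenate([hits, peak_int])

    total = process_in_chunks(dataset, per_spectrum, np.add, plan)
    n = dataset.n_pixels
    freq = total[: len(ref_mz)] / n
    mean_int = total[len(ref_mz):] / n
    return ReferencePeaks(mz=ref_mz, freq=freq, mean_intensity=mean_int)


def filter_reference(ref: ReferencePeaks, min_freq: float = 0.0,
                     min_mean: float = 0.0) -> ReferencePeaks:
    """Keep peaks with frequency >= min_freq and mean intensity > min_mean."""
    keep = (ref.freq >= min_freq) & (ref.mean_intensity > min_mean)
    return ReferencePeaks(ref.mz[keep], ref.freq[keep], ref.mean_intensity[keep])


def integrate_peak_areas(dataset: MSIDataset, ref: ReferencePeaks,
                         tol_ppm: float = 100.0,
                         chunk: int = 256) -> MSIDataset:
    """Trapezoidal peak-area integration (peak binning) onto a centroided set.

    Each reference m/z gets the trapezoidal integral of intensity over axis
    samples within +/-tol_ppm; overlapping windows are truncated at the
    midpoint between adjacent reference m/z (recorded in provenance).
    """
    if dataset.centroided or dataset.mz is None:
        raise ValueError("peak integration requires profile data on a shared axis")
    mz = dataset.mz
    ref_mz = np.asarray(ref.mz, dtype=np.float64)
    half = ref_mz * tol_ppm * 1e-6
    lo_mz = ref_mz - half
    hi_mz = ref_mz + half
    merged = 0
    for k in range(len(ref_mz) - 1):
        mid = 0.5 * (ref_mz[k] + ref_mz[k + 1])
        if hi_mz[k] > mid or lo_mz[k + 1] < mid:
            hi_mz[k] = min(hi_mz[k], mid)
            lo_mz[k + 1] = max(lo_mz[k + 1], mid)
            merged += 1
    los = np.searchsorted(mz, lo_mz, side="left")
    his = np.searchsorted(mz, hi_mz, side="right")

    n = dataset.n_pixels
    out = np.zeros((len(ref_mz), n))
    for c0 in range(0, n, chunk):
        c1 = min(c0 + chunk, n)
        block = dataset.intensity_chunk(np.arange(c0, c1))
        for k in range(len(ref_mz)):
            sl = slice(los[k], his[k])
            if his[k] - los[k] >= 2:
                out[k, c0:c1] = np.trapezoid(block[sl], x=mz[sl], axis=0)
    features = pd.DataFrame({
        "mz": ref_mz, "freq": ref.freq, "mean_intensity": ref.mean_intensity,
    })
    result = MSIDataset(
        intensities=out, mz=ref_mz, pixels=dataset.pixels, features=features,
        centroided=True, provenance=list(dataset.provenance),
    )
    result.provenance.append(result.record(
        "integrate_peak_areas", tol_ppm=tol_ppm, n_peaks=len(ref_mz),
        truncated_windows=merged,
    ))
    return result
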