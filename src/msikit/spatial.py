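"""Pixel neighborhoods, spatial weights, and ion-image rendering.

Spatially-aware segmentation and classification share one weighting scheme:
every pixel gets a square (Chebyshev) neighborhood of radius ``r`` within
its own run; Gaussian weights fall off with Euclidean grid distance with
scale sigma_r = (2r+1)/4, and the adaptive variant additionally down-weights
neighbors whose spectra differ (a bilateral scheme), so that weights respect
tissue boundaries.  Weights are normalized to sum to one per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .dataset import MSIDataset, resolve_feature

__all__ = ["SpatialWeights", "compute_spatial_weights", "render_ion_image"]


@dataclass
class SpatialWeights:
    """Per-pixel neighbor lists and normalized weights.

    ``matrix`` is a sparse (n_pixels x n_pixels) row-stochastic matrix;
    row i holds the weights of pixel i's neighbors (self included).
    """

    r: int
    method: str
    matrix: sparse.csr_matrix

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self.matrix.indices[self.matrix.indptr[i]:self.matrix.indptr[i + 1]]

    def weights(self, i: int) -> np.ndarray:
        return self.matrix.data[self.matrix.indptr[i]:self.matrix.indptr[i + 1]]

    def smooth(self, X: np.ndarray) -> np.ndarray:
        """Weighted neighborhood average of per-pixel rows (n_pixels x p)."""
        return self.matrix @ X


def sigma_r(r: int) -> float:
    """Gaussian kernel scale used for radius r neighborhoods: (2r+1)/4."""
    return (2 * r + 1) / 4.0


def compute_spatial_weights(
    dataset_or_pixels,
    r: int = 1,
    method: str = "gaussian",
    spectra: np.ndarray | None = None,
) -> SpatialWeights:
    """Build normalized spatial weights on the pixel grid.

    Gaussian: alpha_ii' = exp(-d^2 / (2 sigma_r^2)) with d the Euclidean
    grid distance; neighborhoods are Chebyshev balls of radius r within the
    same run.  Adaptive multiplies alpha by
    beta_ii' = exp(-delta_i'^2 / (2 lambda_i^2)) where delta_i' is the
    Euclidean distance between the spectra of pixels i' and i and
    lambda_i = max over the neighborhood of delta (floored at eps).

    ``spectra``: (n_pixels, n_features) array, required for ``adaptive``.
    """
    if method not in ("gaussian", "adaptive"):
        raise ValueError("method must be 'gaussian' or 'adaptive'")
    if r < 0:
        raise ValueError("r must be >= 0")
    pixels = (dataset_or_pixels.pixels
              if isinstance(dataset_or_pixels, MSIDataset) else dataset_or_pixels)
    if method == "adaptive" and spectra is None:
        raise ValueError("adaptive weights require per-pixel spectra")
    n = len(pixels)
    xs = pixels["x"].to_numpy()
    ys = pixels["y"].to_numpy()
    runs = pixels["run"].to_numpy()
    index = {(runs[i], xs[i], ys[i]): i for i in range(n)}
    sig = sigma_r(r)
    rows, cols, vals = [], [], []
    offsets = [(dx, dy) for dx in range(-r, r + 1) for dy in range(-r, r + 1)]
    for i in range(n):
        nbr, w = [], []
        for dx, dy in offsets:
            j = index.get((runs[i], xs[i] + dx, ys[i] + dy))
            if j is None:
                continue
            d2 = dx * dx + dy * dy
            nbr.append(j)
            w.append(np.exp(-d2 / (2.0 * sig * sig)))
        nbr = np.asarray(nbr)
        w = np.asarray(w, dtype=np.float64)
        if method == "adaptive":
            delta = np.linalg.norm(spectra[nbr] - spectra[i], axis=1)
            lam = max(float(delta.max()), np.finfo(float).eps)
            w = w * np.exp(-(delta ** 2) / (2.0 * lam * lam))
        w = w / w.sum()
        rows.extend([i] * len(nbr))
        cols.extend(nbr.tolist())
        vals.extend(w.tolist())
    mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return SpatialWeights(r=r, method=method, matrix=mat)


def _grids(dataset: MSIDataset, values: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for run, grp in dataset.pixels.groupby("run", sort=False):
        w = int(grp["x"].max()) + 1
        h = int(grp["y"].max()) + 1
        img = np.full((h, w), np.nan)
        img[grp["y"].to_numpy(), grp["x"].to_numpy()] = values[grp.index.to_numpy()]
        out[run] = img
    return out


def _nan_gaussian(img: np.ndarray, sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    mask = np.isfinite(img)
    filled = np.where(mask, img, 0.0)
    num = gaussian_filter(filled, sigma)
    den = gaussian_filter(mask.astype(float), sigma)
    out = np.full_like(img, np.nan)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    out[~mask] = np.nan
    return out


def _bilateral(img: np.ndarray, r: int, sigma_s: float) -> np.ndarray:
    """Adaptive (bilateral) smoothing: spatial Gaussian x intensity similarity."""
    h, w = img.shape
    finite = img[np.isfinite(img)]
    if finite.size == 0:
        return img.copy()
    out = img.copy()
    for y in range(h):
        for x in range(w):
            if not np.isfinite(img[y, x]):
                continue
            y0, y1 = max(0, y - r), min(h, y + r + 1)
            x0, x1 = max(0, x - r), min(w, x + r + 1)
            patch = img[y0:y1, x0:x1]
            ok = np.isfinite(patch)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (yy - y) ** 2 + (xx - x) ** 2
            wgt = np.exp(-d2 / (2 * sigma_s ** 2))
            delta = patch - img[y, x]
            lam = max(float(np.nanmax(np.abs(delta))), np.finfo(float).eps)
            wgt = wgt * np.exp(-(delta ** 2) / (2 * lam * lam))
            wgt = np.where(ok, wgt, 0.0)
            out[y, x] = np.nansum(wgt * patch) / wgt.sum()
    return out


def render_ion_image(
    dataset: MSIDataset,
    mz: float,
    tol_ppm: float = 100.0,
    smoothing: str = "none",
    contrast: str = "none",
    normalization: str = "linear",
    r: int = 1,
    suppression_quantile: float = 0.99,
):
    """Render the image of one ion per run, with optional smoothing/contrast.

    Smoothing: ``gaussian`` (2D kernel, sigma_r scale) or ``adaptive``
    (bilateral).  Contrast: ``suppression`` clips above the 99th percentile
    then min-max scales; ``histogram`` is rank-based equalization to
    uniform [0, 1].  ``linear`` normalization is min-max to [0, 1]; a
    degenerate (constant) image maps to all zeros and is flagged.

    Returns (images, flags): dicts keyed by run.
    """
    idx = resolve_feature(dataset, mz, tol_ppm)
    vals = dataset.intensity_chunk(np.arange(dataset.n_pixels))[idx]
    images = _grids(dataset, vals)
    flags: dict[str, list[str]] = {run: [] for run in images}
    sig = sigma_r(r)
    for run, img in images.items():
        if smoothing == "gaussian":
            img = _nan_gaussian(img, sig)
        elif smoothing == "adaptive":
            img = _bilateral(img, r, sig)
        elif smoothing != "none":
            raise ValueError(f"unknown smoothing {smoothing!r}")
        finite = np.isfinite(img)
        if contrast == "suppression":
            clip = np.quantile(img[finite], suppression_quantile)
            img = np.where(finite, np.minimum(img, clip), img)
        elif contrast == "histogram":
            flat = img[finite]
            ranks = np.argsort(np.argsort(flat))
            img = img.copy()
            img[finite] = ranks / max(len(flat) - 1, 1)
        elif contrast != "none":
            raise ValueError(f"unknown contrast {contrast!r}")
        if normalization == "linear" and contrast != "histogram":
            lo = np.nanmin(img)
            hi = np.nanmax(img)
            if hi - lo <= 0:
                img = np.where(finite, 0.0, np.nan)
                flags[run].append("degenerate-range")
            else:
                img = (img - lo) / (hi - lo)
        images[run] = img
    return images, flags


def save_image(img: np.ndarray, path, fmt: str | None = None):
    """Export an image grid as PNG (8-bit gray) or plain matrix CSV."""
    path = str(path)
    fmt = fmt or ("png" if path.lower().endswith(".png") else "csv")
    if fmt == "csv":
        pd.DataFrame(img).to_csv(path, index=False, header=False)
    elif fmt == "png":
        from PIL import Image

        arr = np.nan_to_num(img, nan=0.0)
        lo, hi = arr.min(), arr.max()
        scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        Image.fromarray((scaled * 255).astype(np.uint8)).save(path)
    else:
        raise ValueError(f"unknown image format {fmt!r}")
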