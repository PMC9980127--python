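"""Core MSI dataset container and the chunked map-reduce contract.

An MSI experiment is a grid of pixels, one mass spectrum per pixel.  The
container keeps a feature x pixel intensity matrix (optionally backed by a
lazy store so datasets larger than memory can be processed in pixel chunks),
a pixel table with grid coordinates and annotations, and a feature table
keyed by m/z.  Every processing operation appends one provenance record.
"""

from __future__ import annotations

import datetime as _dt
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MSIDataset",
    "ChunkPlan",
    "ProvenanceRecord",
    "attach_pixel_annotations",
    "subset_pixels",
    "roi_from_rectangles",
    "process_in_chunks",
    "mean_spectrum",
    "summarize_feature",
    "resolve_feature",
]

PIXEL_KEYS = ["run", "x", "y"]


@dataclass(frozen=True)
class ProvenanceRecord:
    name: str
    params: dict
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )


@dataclass(frozen=True)
class ChunkPlan:
    """Pixels-per-chunk and degree of parallelism for chunked reductions."""

    chunk_size: int | None = 256
    workers: int = 1

    def __post_init__(self):
        if self.chunk_size is not None and self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


class _ColumnSubsetStore:
    """Lazy column (pixel) subset view over another intensity store."""

    def __init__(self, base, cols: np.ndarray):
        self._base = base
        self._cols = np.asarray(cols, dtype=np.intp)

    @property
    def shape(self):
        return (self._base.shape[0], len(self._cols))

    def __getitem__(self, key):
        rows, cols = key
        return self._base[rows, self._cols[cols]]


class _ScaledColumnStore:
    """Lazy per-column scaling view (used by TIC normalization)."""

    def __init__(self, base, scale: np.ndarray):
        self._base = base
        self._scale = np.asarray(scale, dtype=np.float64)

    @property
    def shape(self):
        return self._base.shape

    def __getitem__(self, key):
        rows, cols = key
        block = np.asarray(self._base[rows, cols], dtype=np.float64)
        return block * self._scale[cols]


class MSIDataset:
    """Container for one MSI experiment (possibly several runs).

    Parameters
    ----------
    intensities : array-like or lazy store, shape (n_features, n_pixels)
        Must support 2-D slicing ``store[rows, cols]``.  ``None`` for
        processed-mode data without a shared axis (use ``spectra``).
    mz : ndarray or None
        Shared, strictly ascending m/z axis (continuous mode).
    spectra : sequence of (mz, intensity) pairs or callable, optional
        Per-spectrum m/z sampling (processed mode).
    pixels : DataFrame with columns run, x, y plus annotations.
    features : DataFrame with column mz (ascending) plus annotations.
    centroided : whether intensities are discrete peaks rather than profile.
    """

    def __init__(
        self,
        intensities=None,
        mz=None,
        spectra=None,
        pixels: pd.DataFrame | None = None,
        features: pd.DataFrame | None = None,
        centroided: bool = False,
        provenance: list[ProvenanceRecord] | None = None,
    ):
        if intensities is None and spectra is None:
            raise ValueError("need intensities (continuous) or spectra (processed)")
        self._store = intensities
        self._spectra = spectra
        if mz is not None:
            mz = np.asarray(mz, dtype=np.float64)
            if mz.ndim != 1 or (len(mz) > 1 and not np.all(np.diff(mz) > 0)):
                raise ValueError("shared m/z axis must be 1-D strictly increasing")
        self.mz = mz
        if pixels is None:
            raise ValueError("pixel table is required")
        pixels = pixels.reset_index(drop=True)
        for c in PIXEL_KEYS:
            if c not in pixels.columns:
                raise ValueError(f"pixel table missing required column {c!r}")
        if pixels.duplicated(PIXEL_KEYS).any():
            dups = pixels.loc[pixels.duplicated(PIXEL_KEYS), PIXEL_KEYS]
            raise ValueError(f"duplicate (run,x,y) pixels: {dups.values.tolist()}")
        if (pixels["x"] < 0).any() or (pixels["y"] < 0).any():
            raise ValueError("pixel coordinates must be >= 0")
        self.pixels = pixels
        if features is None:
            if mz is None:
                raise ValueError("features table required for processed mode")
            features = pd.DataFrame({"mz": mz})
        features = features.reset_index(drop=True)
        if "mz" not in features.columns:
            raise ValueError("feature table missing column 'mz'")
        if not features["mz"].is_monotonic_increasing:
            raise ValueError("feature table must be sorted ascending by mz")
        self.features = features
        self.centroided = bool(centroided)
        self.provenance = list(provenance or [])
        if self._store is not None:
            f, p = self._store.shape
            if p != len(pixels):
                raise ValueError(
                    f"pixel count {len(pixels)} != intensity columns {p}"
                )
            if f != len(features):
                raise ValueError(
                    f"feature count {len(features)} != intensity rows {f}"
                )

    # -- basic introspection ------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def is_continuous(self) -> bool:
        return self.mz is not None and self._store is not None

    def intensity_chunk(self, cols) -> np.ndarray:
        """Materialize intensity columns (pixels) as float64, shape (F, len(cols))."""
        if self._store is None:
            raise ValueError(
                "processed-mode dataset has no shared intensity matrix; "
                "resample onto a shared axis first"
            )
        return np.asarray(
            self._store[slice(None), np.asarray(cols, dtype=np.intp)],
            dtype=np.float64,
        )

    def intensity_matrix(self) -> np.ndarray:
        """Dense feature x pixel matrix (materializes a lazy store)."""
        return self.intensity_chunk(np.arange(self.n_pixels))

    def spectrum(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(m/z, intensity) arrays of pixel ``i``."""
        if self._store is not None and self.mz is not None:
            return self.mz, self.intensity_chunk([i])[:, 0]
        spec = self._spectra(i) if callable(self._spectra) else self._spectra[i]
        mzs, ints = spec
        return np.asarray(mzs, dtype=np.float64), np.asarray(ints, dtype=np.float64)

    def iter_spectra(self):
        for i in range(self.n_pixels):
            yield self.spectrum(i)

    def _with(self, *, intensities=..., mz=..., spectra=..., pixels=...,
              features=..., centroided=..., step: ProvenanceRecord | None = None):
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return MSIDataset(
            intensities=self._store if intensities is ... else intensities,
            mz=self.mz if mz is ... else mz,
            spectra=self._spectra if spectra is ... else spectra,
            pixels=self.pixels if pixels is ... else pixels,
            features=self.features if features is ... else features,
            centroided=self.centroided if centroided is ... else centroided,
            provenance=prov,
        )

    def record(self, name: str, **params) -> ProvenanceRecord:
        return ProvenanceRecord(name=name, params=params)

    def __repr__(self):
        mode = "centroided" if self.centroided else (
            "continuous" if self.is_continuous else "processed"
        )
        return (
            f"<MSIDataset {mode}: {self.n_features} features x "
            f"{self.n_pixels} pixels, {len(self.provenance)} processing steps>"
        )


def dataset_from_matrix(
    matrix: np.ndarray,
    mz: np.ndarray,
    pixels: pd.DataFrame,
    centroided: bool = False,
    features: pd.DataFrame | None = None,
) -> MSIDataset:
    """Convenience constructor from a dense feature x pixel matrix."""
    return MSIDataset(
        intensities=np.asarray(matrix, dtype=np.float64),
        mz=np.asarray(mz, dtype=np.float64),
        pixels=pixels,
        features=features,
        centroided=centroided,
    )


def grid_pixels(width: int, height: int, run: str = "run0") -> pd.DataFrame:
    """Row-major pixel table for a full rectangular grid (0-based coordinates)."""
    ys, xs = np.divmod(np.arange(width * height), width)
    return pd.DataFrame({"run": run, "x": xs, "y": ys})


# -- annotations ------------------------------------------------------------


def attach_pixel_annotations(dataset: MSIDataset, table: pd.DataFrame) -> MSIDataset:
    """Join per-pixel annotation rows keyed by (run, x, y) onto the pixel table.

    Pixels without a matching row get missing values (pd.NA/NaN); extra rows
    in ``table`` are ignored.  Duplicate keys in ``table`` are an error.
    """
    for c in PIXEL_KEYS:
        if c not in table.columns:
            raise ValueError(f"annotation table missing key column {c!r}")
    dup_mask = table.duplicated(PIXEL_KEYS, keep=False)
    if dup_mask.any():
        dups = table.loc[dup_mask, PIXEL_KEYS].drop_duplicates().values.tolist()
        raise ValueError(f"duplicate (run,x,y) keys in annotation table: {dups}")
    merged = self_merge = dataset.pixels.merge(
        table, on=PIXEL_KEYS, how="left", sort=False, validate="one_to_one"
    )
    assert len(self_merge) == dataset.n_pixels
    new_cols = [c for c in table.columns if c not in PIXEL_KEYS]
    step = dataset.record("attach_pixel_annotations", columns=new_cols)
    return dataset._with(pixels=merged, step=step)


def subset_pixels(dataset: MSIDataset, predicate) -> MSIDataset:
    """Keep exactly the pixels satisfying ``predicate``, in original order.

    ``predicate`` is a pandas query string over pixel-table columns, a boolean
    mask, or a callable DataFrame -> boolean Series.
    """
    px = dataset.pixels
    if isinstance(predicate, str):
        try:
            mask = px.eval(predicate)
        except pd.errors.UndefinedVariableError as e:
            raise ValueError(f"predicate references unknown column: {e}") from e
        mask = np.asarray(mask, dtype=bool)
        desc = predicate
    elif callable(predicate):
        mask = np.asarray(predicate(px), dtype=bool)
        desc = getattr(predicate, "__name__", "<callable>")
    else:
        mask = np.asarray(predicate, dtype=bool)
        desc = "<mask>"
    if mask.shape != (dataset.n_pixels,):
        raise ValueError("predicate mask has wrong length")
    cols = np.flatnonzero(mask)
    step = dataset.record("subset_pixels", predicate=desc, kept=int(len(cols)))
    new_pixels = px.iloc[cols].reset_index(drop=True)
    if dataset._store is not None:
        return dataset._with(
            intensities=_ColumnSubsetStore(dataset._store, cols),
            pixels=new_pixels, step=step,
        )
    base = dataset._spectra
    get = base if callable(base) else base.__getitem__
    return dataset._with(
        spectra=lambda i, _c=cols, _g=get: _g(int(_c[i])),
        pixels=new_pixels, step=step,
    )


def roi_from_rectangles(
    dataset: MSIDataset,
    regions: Sequence[tuple],
    column: str = "roi",
) -> pd.Series:
    """Label pixels by inclusive rectangular regions (run, (x0,x1), (y0,y1), label).

    Pixels covered by no rectangle get missing values.  Two rectangles
    assigning different labels to one pixel is an error.
    """
    px = dataset.pixels
    labels = pd.Series(pd.NA, index=px.index, dtype="object", name=column)
    for run, (x0, x1), (y0, y1), label in regions:
        hit = (
            (px["run"] == run)
            & px["x"].between(int(x0), int(x1))
            & px["y"].between(int(y0), int(y1))
        )
        clash = hit & labels.notna() & (labels != label)
        if clash.any():
            where = px.loc[clash, PIXEL_KEYS].values.tolist()
            raise ValueError(
                f"overlapping ROI rectangles with different labels at pixels {where[:10]}"
            )
        labels[hit] = label
    return labels


# -- chunked map-reduce -----------------------------------------------------


def _pairwise_reduce(values: list, reduce_fn: Callable):
    """Reduce a list by a balanced binary tree (cascade/pairwise order)."""
    while len(values) > 1:
        nxt = []
        for j in range(0, len(values) - 1, 2):
            nxt.append(reduce_fn(values[j], values[j + 1]))
        if len(values) % 2:
            nxt.append(values[-1])
        values = nxt
    return values[0]


def _chunk_ranges(n: int, chunk_size: int | None):
    size = n if chunk_size is None else min(chunk_size, n)
    return [(lo, min(lo + size, n)) for lo in range(0, n, size)]


def process_in_chunks(
    dataset: MSIDataset,
    map_fn: Callable[[np.ndarray], object],
    reduce_fn: Callable,
    plan: ChunkPlan = ChunkPlan(),
):
    """Apply ``map_fn`` to every pixel spectrum and combine with ``reduce_fn``.

    ``reduce_fn`` must be associative and commutative; reductions are done
    pairwise (cascade order) so the result is independent of ``chunk_size``
    and ``workers`` up to floating-point roundoff (<= ~1e-12 relative).
    Peak memory is O(chunk_size x features).
    """
    n = dataset.n_pixels
    if n == 0:
        raise ValueError("cannot reduce over an empty dataset")

    def run_chunk(lo_hi):
        lo, hi = lo_hi
        block = dataset.intensity_chunk(np.arange(lo, hi))
        vals = []
        for j in range(hi - lo):
            try:
                vals.append(map_fn(block[:, j]))
            except Exception as e:  # noqa: BLE001 - re-raised with pixel index
                raise RuntimeError(f"map_fn failed at pixel {lo + j}: {e}") from e
        return _pairwise_reduce(vals, reduce_fn)

    ranges = _chunk_ranges(n, plan.chunk_size)
    if plan.workers == 1 or len(ranges) == 1:
        chunk_vals = [run_chunk(r) for r in ranges]
    else:
        with ThreadPoolExecutor(max_workers=plan.workers) as pool:
            chunk_vals = list(pool.map(run_chunk, ranges))
    return _pairwise_reduce(chunk_vals, reduce_fn)


def mean_spectrum(dataset: MSIDataset, plan: ChunkPlan = ChunkPlan()) -> np.ndarray:
    """Arithmetic mean over pixels of each shared-axis intensity."""
    if not dataset.is_continuous:
        raise ValueError(
            "mean spectrum requires a shared m/z axis; resample processed-mode "
            "data onto regular bins first (resample_ppm_bins)"
        )
    total = process_in_chunks(
        dataset, lambda s: s, lambda a, b: np.add(a, b), plan
    )
    return total / dataset.n_pixels


# -- feature queries --------------------------------------------------------


def resolve_feature(dataset: MSIDataset, mz: float, tol_ppm: float | None = None) -> int:
    """Index of the feature nearest the query m/z (tie -> lower m/z).

    With ``tol_ppm`` set, a query with no feature inside the window is an
    error reporting the nearest available m/z.
    """
    fmz = dataset.features["mz"].to_numpy()
    if len(fmz) == 0:
        raise ValueError("dataset has no features")
    d = np.abs(fmz - mz)
    idx = int(np.argmin(d))  # argmin takes the first (lower-m/z) tie
    if tol_ppm is not None and d[idx] > mz * tol_ppm * 1e-6:
        raise ValueError(
            f"no feature within {tol_ppm} ppm of m/z {mz}; nearest is {fmz[idx]:.6f}"
        )
    return idx


def summarize_feature(
    dataset: MSIDataset,
    mz: float,
    tol_ppm: float,
    groups: str | Sequence[str],
    stat: str = "mean",
) -> pd.DataFrame:
    """Per-group summary (default mean) of the feature nearest the query m/z."""
    if isinstance(groups, str):
        groups = [groups]
    for g in groups:
        if g not in dataset.pixels.columns:
            raise ValueError(f"unknown annotation column {g!r}")
    idx = resolve_feature(dataset, mz, tol_ppm)
    vals = dataset.intensity_chunk(np.arange(dataset.n_pixels))[idx]
    df = dataset.pixels[list(groups)].copy()
    df["value"] = vals
    out = df.groupby(list(groups), dropna=True, observed=True)["value"].agg(stat)
    out = out.reset_index()
    out.insert(0, "mz", dataset.features["mz"].iloc[idx])
    return out
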