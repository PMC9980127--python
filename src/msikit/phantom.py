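"""Synthetic MSI phantom generator with planted ground truth.

The phantom emulates the structure of MALDI imaging experiments: a pixel
grid divided into labeled segments, each segment expressing its own set of
Gaussian-shaped peaks on a geometric (constant-ppm) m/z axis, plus an
exponentially decaying baseline, truncated-Gaussian additive noise,
per-pixel total-ion-current variation, per-spectrum constant-ppm mass
shifts, and an optional global mass-error drift linear in m/z.  Everything
is deterministic given the seed, and the planted truth (segment map, true
peak positions, drift, TIC factors) is returned alongside the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import MSIDataset, grid_pixels

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom", "write_fixture",
           "geometric_axis", "default_segments", "default_peaks"]


def geometric_axis(mz_min: float, mz_max: float, ppm: float) -> np.ndarray:
    """Axis m_{i+1} = m_i * (1 + ppm*1e-6) from mz_min up to mz_max."""
    if ppm <= 0:
        raise ValueError("ppm must be > 0")
    step = 1.0 + ppm * 1e-6
    n = int(np.ceil(np.log(mz_max / mz_min) / np.log(step)))
    return mz_min * step ** np.arange(n + 1)


def default_segments(width: int, height: int):
    """Three rectangular regions on a background, sized relative to the grid."""
    w3, h2 = width // 3, height // 2
    return [
        ("A", (0, w3 - 1), (0, h2 - 1)),
        ("B", (w3, 2 * w3 - 1), (0, h2 - 1)),
        ("C", (0, 2 * w3 - 1), (h2, height - 1)),
    ]


def default_peaks():
    """Per-segment peak recipes: (m/z in Da, amplitude, peak sd in Da)."""
    return {
        "A": [(752.0, 80.0, 0.05), (771.3, 55.0, 0.05)],
        "B": [(760.5, 90.0, 0.05), (781.1, 60.0, 0.05)],
        "C": [(744.2, 70.0, 0.05), (793.4, 65.0, 0.05)],
        "background": [(810.4, 20.0, 0.05)],
        "shared": [(830.0, 40.0, 0.05)],
    }


@dataclass
class PhantomSpec:
    """Declarative recipe for one synthetic MSI run.

    ``peaks`` maps segment labels to lists of (m/z, amplitude, sd_da);
    the special keys "background" (pixels outside every segment) and
    "shared" (added to every pixel) are optional.  ``drift_ppm`` draws a
    per-spectrum constant-ppm mass shift uniformly from the given range;
    ``global_drift_ppm`` plants a mass error linear in m/z, interpolating
    between the ppm error at the axis minimum and at the axis maximum.
    """

    width: int = 12
    height: int = 12
    run: str = "run0"
    segments: Sequence[tuple] | None = None  # (label, (x0,x1), (y0,y1))
    peaks: dict | None = None
    baseline_amp: float = 2.0
    baseline_decay: float = 3.0  # e-folds across the axis
    noise_sd: float = 0.3
    tic_range: tuple[float, float] = (0.9, 1.1)
    drift_ppm: tuple[float, float] = (0.0, 0.0)
    global_drift_ppm: tuple[float, float] | None = None
    mz_min: float = 700.0
    mz_max: float = 900.0
    sampling_ppm: float = 50.0
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("phantom seed is mandatory")
        if self.segments is None:
            self.segments = default_segments(self.width, self.height)
        if self.peaks is None:
            self.peaks = default_peaks()


@dataclass
class GroundTruth:
    """Planted truth for a generated phantom."""

    segment_labels: pd.Series  # per-pixel, aligned with dataset.pixels
    peaks: dict  # label -> [(mz, amplitude, sd_da)]
    shift_ppm: np.ndarray  # per-spectrum constant-ppm shift
    tic_factor: np.ndarray  # per-pixel TIC multiplier
    global_error_da: np.ndarray | None  # planted mass error at each axis point


def _segment_map(spec: PhantomSpec, pixels: pd.DataFrame) -> pd.Series:
    lab = pd.Series("background", index=pixels.index, dtype="object")
    for label, (x0, x1), (y0, y1) in spec.segments:
        hit = pixels["x"].between(x0, x1) & pixels["y"].between(y0, y1)
        lab[hit] = label
    return lab


def _global_error(spec: PhantomSpec, mz: np.ndarray) -> np.ndarray | None:
    if spec.global_drift_ppm is None:
        return None
    p0, p1 = spec.global_drift_ppm
    ppm = p0 + (mz - mz[0]) / (mz[-1] - mz[0]) * (p1 - p0)
    return mz * ppm * 1e-6


def generate_phantom(spec: PhantomSpec) -> tuple[MSIDataset, GroundTruth]:
    """Generate a profile-mode continuous dataset plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    mz = geometric_axis(spec.mz_min, spec.mz_max, spec.sampling_ppm)
    for label, plist in spec.peaks.items():
        for m0, _a, _sd in plist:
            if not (spec.mz_min <= m0 <= spec.mz_max):
                raise ValueError(f"peak m/z {m0} (segment {label!r}) outside axis")
    pixels = grid_pixels(spec.width, spec.height, spec.run)
    n = len(pixels)
    labels = _segment_map(spec, pixels)
    shift = rng.uniform(spec.drift_ppm[0], spec.drift_ppm[1], size=n)
    tic = rng.uniform(spec.tic_range[0], spec.tic_range[1], size=n)
    err = _global_error(spec, mz)

    t = (mz - mz[0]) / (mz[-1] - mz[0])
    baseline = spec.baseline_amp * np.exp(-spec.baseline_decay * t)

    X = np.empty((len(mz), n))
    for i in range(n):
        seg_peaks = list(spec.peaks.get(labels.iloc[i], [])) + list(
            spec.peaks.get("shared", [])
        )
        signal = np.zeros(len(mz))
        for m0, amp, sd in seg_peaks:
            center = m0 * (1.0 + shift[i] * 1e-6)
            if err is not None:
                center = center + np.interp(center, mz, err)
            signal += amp * np.exp(-0.5 * ((mz - center) / sd) ** 2)
        noisy = tic[i] * signal + baseline
        if spec.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sd, size=len(mz))
        X[:, i] = np.maximum(noisy, 0.0)

    ds = MSIDataset(intensities=X, mz=mz, pixels=pixels, centroided=False)
    ds.provenance.append(ds.record("generate_phantom", seed=spec.seed))
    truth = GroundTruth(
        segment_labels=labels,
        peaks=dict(spec.peaks),
        shift_ppm=shift,
        tic_factor=tic,
        global_error_da=err,
    )
    return ds, truth


def generate_centroid_phantom(
    n_pixels_per_group: int | dict,
    group_peaks: dict,
    mz_list: Sequence[float] | None = None,
    noise_sd: float = 0.1,
    width: int | None = None,
    seed: int = 0,
    run: str = "run0",
    layout: str = "blocks",
) -> tuple[MSIDataset, pd.Series]:
    """Centroided phantom: one intensity per (feature, pixel), planted group means.

    ``group_peaks`` maps group label -> {mz: mean intensity}; features are the
    sorted union of all m/z.  ``layout='blocks'`` arranges groups as contiguous
    horizontal bands on a grid so spatial methods see coherent regions.
    Returns (dataset, per-pixel group labels).
    """
    rng = np.random.default_rng(seed)
    groups = list(group_peaks)
    if isinstance(n_pixels_per_group, int):
        n_pixels_per_group = {g: n_pixels_per_group for g in groups}
    if mz_list is None:
        mz_list = sorted({m for d in group_peaks.values() for m in d})
    mz = np.asarray(mz_list, dtype=np.float64)
    counts = [n_pixels_per_group[g] for g in groups]
    n = int(sum(counts))
    if width is None:
        width = max(c for c in counts)
    rows = []
    labels = []
    y0 = 0
    for g, c in zip(groups, counts):
        hrows = int(np.ceil(c / width))
        made = 0
        for dy in range(hrows):
            for x in range(width):
                if made >= c:
                    break
                rows.append((run, x, y0 + dy))
                labels.append(g)
                made += 1
        y0 += hrows
    pixels = pd.DataFrame(rows, columns=["run", "x", "y"])
    lab = pd.Series(labels, name="group")
    X = np.zeros((len(mz), n))
    for j, g in enumerate(lab):
        means = group_peaks[g]
        mu = np.array([means.get(m, 0.0) for m in mz])
        X[:, j] = np.maximum(mu + rng.normal(0, noise_sd, size=len(mz)), 0.0)
    ds = MSIDataset(intensities=X, mz=mz, pixels=pixels, centroided=True)
    return ds, lab


def write_fixture(dataset: MSIDataset, truth: GroundTruth, outdir, mode="continuous",
                  precision: int = 64):
    """Write an imzML fixture pair plus ground-truth CSVs under ``outdir``."""
    from pathlib import Path

    from .io import write_imzml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    imzml = outdir / "phantom.imzML"
    write_imzml(dataset, imzml, mode=mode, precision=precision)
    seg = dataset.pixels[["run", "x", "y"]].copy()
    seg["segment"] = truth.segment_labels.to_numpy()
    seg["shift_ppm"] = truth.shift_ppm
    seg["tic_factor"] = truth.tic_factor
    seg.to_csv(outdir / "truth_pixels.csv", index=False)
    rows = [
        {"segment": g, "mz": m, "amplitude": a, "sd_da": s}
        for g, plist in truth.peaks.items()
        for m, a, s in plist
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth_peaks.csv", index=False)
    return imzml
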