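"""Config-driven pipelines: validate-then-run execution of named steps.

A pipeline config is a mapping with ``seed``, optional ``input``/``output``
paths, and an ordered ``steps`` list of {name, params} records.  Every step
name and parameter is validated against the operation registry before
anything executes, so a failing config never produces partial outputs.
"""

from __future__ import annotations

import inspect
import json
import sys
import time
from pathlib import Path

import numpy as np

from . import calibrate, peaks, preprocess
from .dataset import MSIDataset
from .io import read_imzml, write_imzml
from .phantom import PhantomSpec, generate_phantom

__all__ = ["PipelineConfig", "run_pipeline", "PipelineValidationError", "REGISTRY"]


class PipelineValidationError(ValueError):
    pass


def _step_phantom(ds, *, seed, **kw):
    spec = PhantomSpec(seed=seed, **kw)
    out, _truth = generate_phantom(spec)
    return out


def _step_smooth(ds, *, window=9, sd=2.0):
    return preprocess.smooth_dataset(ds, preprocess.SmoothingParams(window, sd))


def _step_baseline(ds, *, blocks=750):
    return preprocess.remove_baseline_dataset(ds, preprocess.BaselineParams(blocks))


def _step_normalize(ds, *, method="tic"):
    if method != "tic":
        raise PipelineValidationError(f"unknown normalization {method!r}")
    return preprocess.normalize_tic(ds)


def _step_resample(ds, *, ppm=10.0):
    return preprocess.resample_ppm_bins(ds, ppm)


def _step_align(ds, *, tol_ppm=200.0, anchors=20):
    out, _rep = calibrate.mz_align_to_mean(
        ds, calibrate.CalibrationParams(tol_ppm=tol_ppm, anchors=anchors))
    return out


def _step_recalibrate(ds, *, calibrants, tol_ppm=200.0):
    out, _rep = calibrate.recalibrate_internal(
        ds, calibrate.CalibrationParams(tol_ppm=tol_ppm,
                                        calibrants=tuple(sorted(calibrants))))
    return out


def _step_peaks(ds, *, method="mad", snr=6.0, window=5, blocks=100,
                tol_ppm=15.0, min_freq=0.0, min_mean=0.0, integrate_ppm=100.0):
    ref = peaks.build_reference(
        ds, peaks.PeakDetectParams(method=method, snr=snr, window=window,
                                   blocks=blocks), tol_ppm)
    ref = peaks.filter_reference(ref, min_freq=min_freq, min_mean=min_mean)
    return peaks.integrate_peak_areas(ds, ref, tol_ppm=integrate_ppm)


def _step_ssc_segment(ds, *, r=2, k=10, s=0.0, seed=0, max_iter=100):
    from .ssc import ssc_segment

    fit = ssc_segment(ds, r=r, k=k, s=s, seed=seed, max_iter=max_iter)
    ds.pixels["ssc_segment"] = np.asarray(fit.labels_)
    return ds


def _step_dgmm(ds, *, mz, tol_ppm=100.0, r=1, k=2, annealing=False, seed=0):
    from .dgmm import dgmm_segment

    fit = dgmm_segment(ds, mz, tol_ppm=tol_ppm, r=r, k=k,
                       annealing=annealing, seed=seed)
    ds.pixels["dgmm_segment"] = fit.labels_
    return ds


REGISTRY = {
    "phantom": _step_phantom,
    "smooth": _step_smooth,
    "baseline": _step_baseline,
    "normalize": _step_normalize,
    "resample": _step_resample,
    "align": _step_align,
    "recalibrate": _step_recalibrate,
    "peaks": _step_peaks,
    "ssc-segment": _step_ssc_segment,
    "dgmm": _step_dgmm,
}


class PipelineConfig:
    """Validated pipeline configuration."""

    def __init__(self, config: dict):
        if not isinstance(config, dict):
            raise PipelineValidationError("config must be a mapping")
        unknown_top = set(config) - {"seed", "input", "output", "steps",
                                     "chunk_size", "workers"}
        if unknown_top:
            raise PipelineValidationError(f"unknown config keys: {sorted(unknown_top)}")
        steps = config.get("steps")
        if not isinstance(steps, list) or not steps:
            raise PipelineValidationError("config needs a non-empty 'steps' list")
        self.seed = int(config.get("seed", 0))
        self.input = config.get("input")
        self.output = config.get("output")
        self.steps = []
        for rec in steps:
            name = rec.get("name")
            params = dict(rec.get("params", {}))
            if name not in REGISTRY:
                raise PipelineValidationError(
                    f"unknown step {name!r}; known: {sorted(REGISTRY)}")
            fn = REGISTRY[name]
            if name == "phantom":
                import dataclasses

                allowed = {f.name for f in dataclasses.fields(PhantomSpec)}
            else:
                sig = inspect.signature(fn)
                allowed = {p for p in sig.parameters if p not in ("ds",)}
            extra = set(params) - allowed
            if extra:
                raise PipelineValidationError(
                    f"step {name!r}: unknown parameters {sorted(extra)}; "
                    f"allowed: {sorted(allowed)}")
            self.steps.append((name, params))


def run_pipeline(config: dict | PipelineConfig, log=sys.stderr):
    """Validate then execute a pipeline; returns the final dataset.

    Writes a machine-readable run manifest beside the output (if an output
    path is configured).
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(config)
    ds: MSIDataset | None = None
    if cfg.input:
        ds = read_imzml(cfg.input)
    manifest = {"seed": cfg.seed, "steps": []}
    for name, params in cfg.steps:
        t0 = time.perf_counter()
        call = dict(params)
        if name == "phantom" and "seed" not in call:
            call["seed"] = cfg.seed
        if name in ("ssc-segment", "dgmm") and "seed" not in call:
            call["seed"] = cfg.seed
        ds = REGISTRY[name](ds, **call)
        dt = time.perf_counter() - t0
        print(f"[msikit] step {name} done in {dt:.2f}s", file=log)
        manifest["steps"].append({"name": name, "params": params,
                                  "seconds": round(dt, 4)})
    if cfg.output:
        out = Path(cfg.output)
        out.parent.mkdir(parents=True, exist_ok=True)
        write_imzml(ds, out, mode="continuous" if ds.is_continuous else "processed")
        with open(out.with_suffix(".manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return ds
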