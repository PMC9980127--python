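"""imzML/ibd reading, writing and validation.

Continuous mode stores one shared m/z array for all spectra; processed mode
stores a per-spectrum m/z array.  Reading is lazy: spectra are pulled from
the ibd file on demand, so datasets larger than memory can be chunked
through :func:`msikit.dataset.process_in_chunks`.  Parsing and writing stand
on pyimzml; validation re-reads the XML directly to check the binary-layout
invariants (uuid match, offset bounds, overlap, shared-axis rule).
"""

from __future__ import annotations

import re
import uuid as _uuid
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .dataset import MSIDataset

__all__ = ["read_imzml", "write_imzml", "validate_imzml", "ImzmlReport"]

_NS = "{http://psi.hupo.org/ms/mzml}"
# imzML controlled-vocabulary accessions
_ACC_UUID = "IMS:1000080"
_ACC_CONTINUOUS = "IMS:1000030"
_ACC_PROCESSED = "IMS:1000031"
_ACC_OFFSET = "IMS:1000102"
_ACC_ARRAY_LEN = "IMS:1000103"
_ACC_ENCODED_LEN = "IMS:1000104"

_DTYPES = {32: np.dtype("<f4"), 64: np.dtype("<f8")}


def _ibd_path(path: Path) -> Path:
    for ext in (".ibd", ".IBD"):
        p = path.with_suffix(ext)
        if p.exists():
            return p
    raise FileNotFoundError(f"no sibling .ibd file for {path}")


def _xml_uuid(imzml_path: Path) -> str | None:
    for _ev, el in etree.iterparse(str(imzml_path), tag=f"{_NS}cvParam"):
        if el.get("accession") == _ACC_UUID:
            return re.sub(r"[{}\-]", "", el.get("value", "")).lower()
    return None


def _check_uuid(imzml_path: Path, ibd_path: Path):
    xml_uuid = _xml_uuid(imzml_path)
    with open(ibd_path, "rb") as fh:
        ibd_uuid = fh.read(16).hex()
    if xml_uuid is None:
        raise ValueError(f"{imzml_path}: no uuid cvParam in XML")
    if xml_uuid != ibd_uuid:
        raise ValueError(
            f"uuid mismatch: XML declares {xml_uuid} but ibd starts with {ibd_uuid}"
        )
    return xml_uuid


class _LazyContinuousStore:
    """Feature x pixel view over a continuous-mode ibd file."""

    def __init__(self, ibd_path, offsets, lengths, dtype, n_features):
        self._ibd = Path(ibd_path)
        self._offsets = offsets
        self._lengths = lengths
        self._dtype = dtype
        self._n_features = n_features

    @property
    def shape(self):
        return (self._n_features, len(self._offsets))

    def __getitem__(self, key):
        rows, cols = key
        cols = np.atleast_1d(np.asarray(cols, dtype=np.intp))
        out = np.empty((self._n_features, len(cols)), dtype=np.float64)
        with open(self._ibd, "rb") as fh:
            for j, c in enumerate(cols):
                fh.seek(self._offsets[c])
                buf = fh.read(self._lengths[c] * self._dtype.itemsize)
                out[:, j] = np.frombuffer(buf, dtype=self._dtype)
        return out[rows]


def read_imzml(path, run: str | None = None) -> MSIDataset:
    """Read an imzML/ibd pair into a lazily backed :class:`MSIDataset`.

    Coordinates are converted from the 1-based imzML convention to the
    internal 0-based convention.  ``run`` defaults to the file stem.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    ibd = _ibd_path(path)
    _check_uuid(path, ibd)
    parser = ImzMLParser(str(path))
    ibd_size = ibd.stat().st_size
    n = len(parser.coordinates)
    for i in range(n):
        for off, length, prec in (
            (parser.mzOffsets[i], parser.mzLengths[i], parser.mzPrecision),
            (parser.intensityOffsets[i], parser.intensityLengths[i],
             parser.intensityPrecision),
        ):
            end = off + length * np.dtype(prec).itemsize
            if end > ibd_size:
                raise ValueError(
                    f"spectrum {i}: binary array [{off}, {end}) extends past "
                    f"end of ibd ({ibd_size} bytes)"
                )
    run = run if run is not None else path.stem
    coords = np.asarray([(c[0], c[1]) for c in parser.coordinates])
    pixels = pd.DataFrame({"run": run, "x": coords[:, 0] - 1, "y": coords[:, 1] - 1})

    continuous = len(set(parser.mzOffsets)) == 1
    if continuous:
        mz = np.asarray(parser.getspectrum(0)[0], dtype=np.float64)
        store = _LazyContinuousStore(
            ibd,
            parser.intensityOffsets,
            parser.intensityLengths,
            np.dtype(parser.intensityPrecision).newbyteorder("<"),
            len(mz),
        )
        ds = MSIDataset(intensities=store, mz=mz, pixels=pixels)
    else:
        def _get(i, _p=parser):
            m, x = _p.getspectrum(i)
            return np.asarray(m, np.float64), np.asarray(x, np.float64)

        # processed mode has no shared feature axis; feature table left empty
        fmz = pd.DataFrame({"mz": pd.Series([], dtype=float)})
        ds = MSIDataset(spectra=_get, pixels=pixels, features=fmz)
    ds.provenance.append(ds.record("read_imzml", path=str(path)))
    return ds


def write_imzml(dataset: MSIDataset, path, mode: str = "continuous",
                precision: int = 64) -> Path:
    """Write ``dataset`` as a standard imzML/ibd pair (little-endian floats).

    Continuous mode requires a shared m/z axis and stores it once; a fresh
    uuid is generated for every file.  Coordinates are written 1-based.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if mode not in ("continuous", "processed"):
        raise ValueError("mode must be 'continuous' or 'processed'")
    if precision not in _DTYPES:
        raise ValueError("precision must be 32 or 64")
    if mode == "continuous" and dataset.mz is None:
        raise ValueError(
            "continuous mode requires a shared m/z axis; this dataset has "
            "per-spectrum axes (write mode='processed' or resample first)"
        )
    path = Path(path)
    dt = np.float32 if precision == 32 else np.float64
    spec_type = "centroid" if dataset.centroided else "profile"
    with ImzMLWriter(str(path), mz_dtype=dt, intensity_dtype=dt, mode=mode,
                     spec_type=spec_type) as w:
        for i in range(dataset.n_pixels):
            mzs, ints = dataset.spectrum(i)
            x = int(dataset.pixels["x"].iloc[i]) + 1
            y = int(dataset.pixels["y"].iloc[i]) + 1
            w.addSpectrum(mzs, ints, (x, y, 1))
    return path


@dataclass
class ImzmlReport:
    """Validation report for one imzML/ibd pair."""

    path: str
    mode: str | None = None
    mz_precision: int | None = None
    intensity_precision: int | None = None
    n_spectra: int = 0
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


_PRECISION_NAMES = {"32-bit float": 32, "64-bit float": 64}


def validate_imzml(path) -> ImzmlReport:
    """Check an imzML/ibd pair against the format's structural invariants.

    Problems (uuid mismatch, out-of-bounds or overlapping binary regions,
    continuous files with more than one m/z array record) are collected in
    the report, not raised; only unreadable XML raises.
    """
    path = Path(path)
    rpt = ImzmlReport(path=str(path))
    tree = etree.parse(str(path))  # raises on malformed XML
    root = tree.getroot()

    def cv_values(accession):
        return root.findall(f".//{_NS}cvParam[@accession='{accession}']")

    if cv_values(_ACC_CONTINUOUS):
        rpt.mode = "continuous"
    elif cv_values(_ACC_PROCESSED):
        rpt.mode = "processed"
    else:
        rpt.violations.append("neither continuous nor processed mode declared")

    for el in root.findall(f".//{_NS}referenceableParamGroup"):
        names = {c.get("name") for c in el.findall(f"{_NS}cvParam")}
        for nm, bits in _PRECISION_NAMES.items():
            if nm in names:
                if "m/z array" in {c.get("name") for c in el.findall(f"{_NS}cvParam")}:
                    rpt.mz_precision = bits
                else:
                    rpt.intensity_precision = rpt.intensity_precision or bits

    try:
        ibd = _ibd_path(path)
    except FileNotFoundError:
        rpt.violations.append("missing sibling .ibd file")
        return rpt
    xml_uuid = _xml_uuid(path)
    with open(ibd, "rb") as fh:
        ibd_uuid = fh.read(16).hex()
    if xml_uuid is None:
        rpt.violations.append("no uuid cvParam in XML")
    elif xml_uuid != ibd_uuid:
        rpt.violations.append(
            f"uuid mismatch (XML {xml_uuid} vs ibd {ibd_uuid})"
        )
    ibd_size = ibd.stat().st_size

    spectra = root.findall(f".//{_NS}spectrum")
    rpt.n_spectra = len(spectra)
    regions = []  # (offset, end, spectrum index, which array)
    mz_records = set()
    for i, sp in enumerate(spectra):
        for arr in sp.findall(f".//{_NS}binaryDataArray"):
            params = {c.get("accession"): c.get("value")
                      for c in arr.findall(f".//{_NS}cvParam")}
            names = {c.get("name") for c in arr.findall(f".//{_NS}cvParam")}
            off = params.get(_ACC_OFFSET)
            enc = params.get(_ACC_ENCODED_LEN)
            if off is None or enc is None:
                rpt.violations.append(f"spectrum {i}: missing offset/length")
                continue
            off, enc = int(off), int(enc)
            kind = "mz" if "m/z array" in names else "intensity"
            if kind == "mz":
                mz_records.add((off, enc))
            if off + enc > ibd_size:
                rpt.violations.append(
                    f"spectrum {i} {kind} array [{off}, {off + enc}) past end "
                    f"of ibd ({ibd_size} bytes)"
                )
            regions.append((off, off + enc, i, kind))
    regions.sort()
    deduped = []
    for reg in regions:  # continuous mode legitimately repeats the m/z record
        if deduped and deduped[-1][:2] == reg[:2]:
            continue
        deduped.append(reg)
    for a, b in zip(deduped, deduped[1:]):
        if b[0] < a[1]:
            rpt.violations.append(
                f"overlapping binary regions: spectrum {a[2]} {a[3]} "
                f"[{a[0]},{a[1]}) and spectrum {b[2]} {b[3]} [{b[0]},{b[1]})"
            )
    if rpt.mode == "continuous" and len(mz_records) > 1:
        rpt.violations.append(
            f"continuous mode but {len(mz_records)} distinct m/z array records"
        )
    return rpt
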