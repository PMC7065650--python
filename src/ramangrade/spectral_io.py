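"""On-disk formats for hyperspectral maps, spectra, models and prediction maps.

Formats
-------
* HDF5, one biopsy per file: datasets ``/axis`` (1-D), ``/intensity``
  (n_pixels x n_wavenumbers), ``/coords`` (n_pixels x 2 int, 0-based
  row-major grid indices) and a ``/meta`` group whose attributes carry the
  biopsy metadata.  Lossless at full float precision.
* Long CSV with columns ``biopsy_id,row,col,wavenumber,intensity`` — slower
  and larger, but diff-able; floats are written with full repr precision.
* JCAMP-DX import for single reference spectra (calibration standards);
  only the uncompressed AFFN numeric form is supported.
* Model archives: NumPy ``.npz`` with a JSON metadata record and an explicit
  format-version field; round-trips reproduce predictions bit-exactly.
* Prediction maps as CSV ``row,col,mean_prediction,assignment``.

Readers reject inconsistent inputs rather than repairing them.
"""

from __future__ import annotations

import json
import re
import zipfile
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .chemometrics import FORMAT_VERSION, PLSLDAModel
from .types import (
    HyperspectralMap,
    PredictionMap,
    Spectrum,
    WavenumberAxis,
    assignment_from_mean,
)

__all__ = [
    "read_map",
    "write_map",
    "read_jcampdx",
    "serialize_model",
    "load_model",
    "write_prediction_map",
    "read_prediction_map",
]


def write_map(hsmap: HyperspectralMap, path: str | Path, format: str = "hdf5") -> None:
    """Write one biopsy map; ``format`` is ``"hdf5"`` or ``"long-csv"``."""
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("axis", data=hsmap.axis.values)
            f.create_dataset("intensity", data=hsmap.intensities)
            f.create_dataset("coords", data=hsmap.coords.astype(np.int64))
            meta = f.create_group("meta")
            for k, v in hsmap.meta.items():
                meta.attrs[k] = v
    elif format == "long-csv":
        n_px, n_wn = hsmap.intensities.shape
        df = pd.DataFrame(
            {
                "biopsy_id": np.repeat(hsmap.biopsy_id, n_px * n_wn),
                "row": np.repeat(hsmap.coords[:, 0], n_wn),
                "col": np.repeat(hsmap.coords[:, 1], n_wn),
                "wavenumber": np.tile(hsmap.axis.values, n_px),
                "intensity": hsmap.intensities.ravel(),
            }
        )
        with path.open("w", newline="") as fh:
            fh.write(f"# patient_id={hsmap.patient_id} histo_label={hsmap.histo_label}\n")
            df.to_csv(fh, index=False, float_format=lambda x: repr(float(x)))
    else:
        raise ValueError(f"unknown map format {format!r}")


def read_map(path: str | Path, format: str = "hdf5") -> HyperspectralMap:
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            for name in ("axis", "intensity", "coords"):
                if name not in f:
                    raise ValueError(f"malformed map file: missing dataset '{name}'")
            axis = WavenumberAxis(f["axis"][()])
            intensities = f["intensity"][()]
            coords = f["coords"][()]
            meta: dict[str, Any] = {}
            if "meta" in f:
                meta = {k: _from_h5(v) for k, v in f["meta"].attrs.items()}
        return HyperspectralMap(axis, intensities, coords, meta)
    if format == "long-csv":
        with Path(path).open() as fh:
            header = fh.readline()
            m = re.match(r"#\s*patient_id=(\S*)\s+histo_label=(\S*)", header)
            if not m:
                raise ValueError("malformed map file: missing metadata header line")
            df = pd.read_csv(fh, float_precision="round_trip")
        for col in ("biopsy_id", "row", "col", "wavenumber", "intensity"):
            if col not in df.columns:
                raise ValueError(f"malformed map file: missing column '{col}'")
        if df.duplicated(subset=["row", "col", "wavenumber"]).any():
            raise ValueError("malformed map file: duplicated (row, col) pixel entries")
        axis_values = np.sort(df["wavenumber"].unique())
        pixels = df[["row", "col"]].drop_duplicates().to_numpy()
        wide = df.pivot_table(
            index=["row", "col"], columns="wavenumber", values="intensity", sort=False
        ).sort_index(axis=1)
        if wide.isna().any().any():
            raise ValueError("malformed map file: incomplete spectrum for some pixel")
        order = pd.MultiIndex.from_arrays([pixels[:, 0], pixels[:, 1]])
        wide = wide.loc[order]
        meta = {
            "biopsy_id": str(df["biopsy_id"].iloc[0]),
            "patient_id": m.group(1),
            "histo_label": m.group(2),
        }
        return HyperspectralMap(WavenumberAxis(axis_values), wide.to_numpy(), pixels, meta)
    raise ValueError(f"unknown map format {format!r}")


def _from_h5(v: Any) -> Any:
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


# --------------------------------------------------------------------------
# JCAMP-DX

_AFFN_TOKEN = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
_COMPRESSED = re.compile(r"[@A-DF-Za-df-z%]")  # SQZ/DIF/DUP digit forms ('E'/'e' is AFFN exponent)


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a single spectrum from a JCAMP-DX file.

    Supports ``##XYPOINTS=(XY..XY)`` and ``##XYDATA=(X++(Y..Y))`` in plain
    AFFN form; the SQZ/DIF/DUP compressed dialects are rejected explicitly.
    The returned axis is ascending (stored order is reversed if needed) and
    must be in cm^-1 (``##XUNITS=1/CM``).
    """
    labels: dict[str, str] = {}
    data_label: str | None = None
    data_lines: list[str] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("##"):
            name, _, value = line[2:].partition("=")
            name = name.strip().upper().replace(" ", "")
            if name in ("XYDATA", "XYPOINTS"):
                data_label = name
                in_data = True
                continue
            in_data = False
            if name == "END":
                break
            labels[name] = value.strip()
        elif in_data:
            data_lines.append(line)
    if data_label is None:
        raise ValueError("JCAMP-DX file contains no XYDATA or XYPOINTS block")
    if "XUNITS" not in labels:
        raise ValueError("JCAMP-DX file is missing the required ##XUNITS label")
    xunits = labels["XUNITS"].upper()
    if "1/CM" not in xunits and "CM-1" not in xunits:
        raise ValueError(f"unsupported XUNITS {labels['XUNITS']!r}; expected 1/CM")
    xfactor = float(labels.get("XFACTOR", "1"))
    yfactor = float(labels.get("YFACTOR", "1"))

    body = " ".join(data_lines)
    check = _AFFN_TOKEN.sub(" ", body).replace(",", " ").replace(";", " ")
    if _COMPRESSED.search(check):
        raise ValueError(
            "unsupported JCAMP-DX dialect: compressed (SQZ/DIF/DUP) data are not handled"
        )

    if data_label == "XYPOINTS":
        nums = [float(t) for t in _AFFN_TOKEN.findall(body)]
        if len(nums) % 2:
            raise ValueError("XYPOINTS block has an odd number of values")
        xv = np.asarray(nums[0::2], dtype=float)  # XYPOINTS carry real units
        yv = np.asarray(nums[1::2], dtype=float)
    else:  # XYDATA=(X++(Y..Y)): each line starts with X, rest are Y at fixed step
        npoints = int(float(labels.get("NPOINTS", "0")))
        firstx = float(labels.get("FIRSTX", "nan"))
        lastx = float(labels.get("LASTX", "nan"))
        rows = [[float(t) for t in _AFFN_TOKEN.findall(ln)] for ln in data_lines]
        ys = [v for r in rows for v in r[1:]]
        n = npoints or len(ys)
        if len(ys) != n:
            raise ValueError(f"XYDATA block has {len(ys)} points, NPOINTS says {n}")
        if not np.isfinite(firstx) or not np.isfinite(lastx):
            raise ValueError("XYDATA requires FIRSTX and LASTX labels")
        xv = np.linspace(firstx, lastx, n)  # grid from FIRSTX/LASTX, already real units
        yv = np.asarray(ys, dtype=float) * yfactor
    if xv.size >= 2 and xv[0] > xv[-1]:
        xv = xv[::-1]
        yv = yv[::-1]
    return Spectrum(WavenumberAxis(xv), yv)


# --------------------------------------------------------------------------
# Model archives

_MODEL_ARRAYS = (
    "axis_values",
    "x_mean",
    "pls_weights",
    "pls_loadings",
    "rotation",
    "lda_direction",
    "coefficient_spectrum",
)


def serialize_model(model: PLSLDAModel, path: str | Path) -> None:
    """Write a PLS-LDA model as a self-describing single-file archive."""
    meta = {
        "format_version": model.format_version,
        "n_components": model.n_components,
        "lda_intercept": model.lda_intercept,
        "class_codes": list(model.class_codes),
        "class_labels": list(model.class_labels),
        "training_fingerprint": model.training_fingerprint,
    }
    arrays = {name: getattr(model, name) for name in _MODEL_ARRAYS}
    np.savez(path, meta_json=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> PLSLDAModel:
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
            arrays = {name: data[name] for name in _MODEL_ARRAYS}
    except (OSError, ValueError, KeyError, EOFError, zipfile.BadZipFile, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot load model archive {path}: {exc}") from exc
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"model archive format version {version} does not match "
            f"supported version {FORMAT_VERSION}"
        )
    return PLSLDAModel(
        n_components=int(meta["n_components"]),
        lda_intercept=float(meta["lda_intercept"]),
        class_codes=tuple(meta["class_codes"]),
        class_labels=tuple(meta["class_labels"]),
        training_fingerprint=meta["training_fingerprint"],
        format_version=int(version),
        **arrays,
    )


# --------------------------------------------------------------------------
# Prediction maps


def write_prediction_map(pmap: PredictionMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "row": pmap.coords[:, 0],
            "col": pmap.coords[:, 1],
            "mean_prediction": pmap.mean_prediction,
            "assignment": pmap.assignment,
        }
    ).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_prediction_map(path: str | Path) -> PredictionMap:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("row", "col", "mean_prediction", "assignment"):
        if col not in df.columns:
            raise ValueError(f"malformed prediction map: missing column '{col}'")
    coords = df[["row", "col"]].to_numpy()
    mean_pred = df["mean_prediction"].to_numpy(dtype=float)
    expected = np.array([assignment_from_mean(v) for v in mean_pred], dtype=object)
    given = df["assignment"].to_numpy(dtype=object)
    if not np.array_equal(expected, given):
        raise ValueError("malformed prediction map: assignment violates the 1.5 rule")
    return PredictionMap(coords, mean_pred, given)
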