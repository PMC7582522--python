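"""File-format adapters: point tables and traces as CSV, images as TIFF,
ROI polygons as CSV vertex lists, ground truth / results as JSON.

All tables round-trip losslessly.  Synthetic images are written as 16-bit
grayscale TIFF (matching common confocal exports) with a JSON sidecar
carrying the µm calibration and origin.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import FluorescenceImage, NetworkPointSet, RoiPolygon
from .ephys import CurrentTraceSet

__all__ = [
    "write_points", "read_points",
    "write_traces", "read_traces",
    "write_image", "read_image",
    "write_roi", "read_roi",
    "write_json", "read_json",
]

POINT_COLUMNS = ["x_um", "y_um", "is_patched"]


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


def write_points(path, points: NetworkPointSet) -> None:
    """Write a point table CSV with columns x_um, y_um, is_patched."""
    rows = points.all_points()
    df = pd.DataFrame(
        {
            "x_um": rows[:, 0],
            "y_um": rows[:, 1],
            "is_patched": [1] + [0] * points.n_coupled,
        }
    )
    df.to_csv(path, index=False)


def read_points(path) -> NetworkPointSet:
    df = pd.read_csv(path)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    patched = df[df["is_patched"] == 1]
    if len(patched) != 1:
        raise SchemaError(f"{path}: expected exactly one patched cell, got {len(patched)}")
    cells = df[df["is_patched"] != 1]
    return NetworkPointSet(
        patched=patched[["x_um", "y_um"]].to_numpy()[0],
        cells=cells[["x_um", "y_um"]].to_numpy(),
    )


def write_traces(path, traces: CurrentTraceSet) -> None:
    """Trace CSV: first column time_ms, one column per command voltage (mV)."""
    df = pd.DataFrame(
        traces.currents_na.T, columns=[f"{v:g}" for v in traces.command_voltages]
    )
    df.insert(0, "time_ms", traces.time_ms)
    df.to_csv(path, index=False)


def read_traces(path, step_onset_ms: float = 10.0) -> CurrentTraceSet:
    df = pd.read_csv(path)
    if df.columns[0] != "time_ms":
        raise SchemaError(f"{path}: first column must be time_ms")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise SchemaError(f"{path}: time column must be strictly increasing")
    try:
        commands = np.array([float(c) for c in df.columns[1:]])
    except ValueError as e:
        raise SchemaError(f"{path}: trace headers must be command voltages in mV") from e
    currents = df.iloc[:, 1:].to_numpy(dtype=float).T
    return CurrentTraceSet(t, currents, commands, step_onset_ms=step_onset_ms)


def write_image(path, image: FluorescenceImage, bit_depth: int = 16) -> None:
    """Write a single-channel TIFF (uint16 by default) plus a JSON sidecar."""
    if bit_depth == 16:
        data = np.clip(np.rint(image.intensities), 0, 65535).astype(np.uint16)
    elif bit_depth == 8:
        data = np.clip(np.rint(image.intensities), 0, 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    res = 1.0 / image.pixel_size  # pixels per µm
    tifffile.imwrite(path, data, resolution=(res, res))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"pixel_size_um": image.pixel_size, "origin_um": list(image.origin)})
    )


def read_image(path, pixel_size: float | None = None) -> FluorescenceImage:
    """Read a TIFF; calibration from the JSON sidecar or ``pixel_size``."""
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    origin = (0.0, 0.0)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = meta.get("pixel_size_um", pixel_size)
        origin = tuple(meta.get("origin_um", origin))
    if pixel_size is None:
        raise ValueError(f"{path}: no calibration sidecar; pass pixel_size explicitly")
    return FluorescenceImage(data, pixel_size=pixel_size, origin=origin)


def write_roi(path, roi: RoiPolygon) -> None:
    df = pd.DataFrame(roi.vertices, columns=["x_um", "y_um"])
    df.insert(0, "label", roi.label)
    df.to_csv(path, index=False)


def read_roi(path) -> RoiPolygon:
    df = pd.read_csv(path)
    for c in ("x_um", "y_um"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing column {c}")
    label = str(df["label"].iloc[0]) if "label" in df.columns else ""
    return RoiPolygon(df[["x_um", "y_um"]].to_numpy(), label=label)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
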