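"""File I/O: multi-page TIFF volumes and stacks, CSV curves/tables, JSON metrics.

Volumes are stored as multi-page TIFF (one z-slice per page) with a JSON
metadata sidecar embedded in the TIFF description tag carrying the voxel
size and provenance; curves as CSV at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FileFormatError
from .phantom import LabeledVolume, RIVolume
from .quality import MTFCurve, StripeSeries

__all__ = [
    "write_labeled_volume",
    "read_labeled_volume",
    "write_ri_volume",
    "read_ri_volume",
    "write_mtf_csv",
    "read_mtf_csv",
    "write_stripe_series",
    "read_stripe_series",
    "write_metrics_json",
    "read_metrics_json",
]


def _write_tiff(path, array, meta: dict):
    tifffile.imwrite(path, array, description=json.dumps(meta))


def _read_tiff(path) -> tuple[np.ndarray, dict]:
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description or "{}"
        meta = json.loads(desc) if desc.strip().startswith("{") else {}
        return arr, meta
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise FileFormatError(f"cannot read TIFF volume from {path}: {exc}") from exc


def write_labeled_volume(labels: LabeledVolume, path) -> None:
    _write_tiff(path, labels.labels.astype(np.int32), {"voxel_size_um": labels.voxel_size_um})


def read_labeled_volume(path) -> LabeledVolume:
    arr, meta = _read_tiff(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FileFormatError(f"{path}: label volume must be integer-typed, got {arr.dtype}")
    return LabeledVolume(arr.astype(np.int32), float(meta.get("voxel_size_um", 1.0)))


def write_ri_volume(ri: RIVolume, path) -> None:
    meta = {
        "voxel_size_um": ri.voxel_size_um,
        "model": ri.model,
        "seed": ri.seed,
        "smoothed": ri.smoothed,
        "chromocenter_counts": {str(k): v for k, v in ri.chromocenter_counts.items()},
    }
    _write_tiff(path, ri.ri.astype(np.float32), meta)


def read_ri_volume(path) -> RIVolume:
    arr, meta = _read_tiff(path)
    return RIVolume(
        arr.astype(np.float32),
        float(meta.get("voxel_size_um", 1.0)),
        model=str(meta.get("model", "unknown")),
        seed=meta.get("seed"),
        chromocenter_counts={int(k): int(v) for k, v in meta.get("chromocenter_counts", {}).items()},
        smoothed=bool(meta.get("smoothed", False)),
    )


def write_mtf_csv(curve: MTFCurve, path) -> None:
    curve.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_mtf_csv(path) -> MTFCurve:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError, OSError) as exc:
        raise FileFormatError(f"cannot read MTF CSV from {path}: {exc}") from exc
    if "frequency_cpd" not in df.columns or "mtf" not in df.columns:
        raise FileFormatError(f"{path}: expected columns frequency_cpd, mtf")
    ci = None
    if {"ci_lo", "ci_hi"} <= set(df.columns):
        ci = df[["ci_lo", "ci_hi"]].to_numpy()
    return MTFCurve(
        frequencies_cpd=df["frequency_cpd"].to_numpy(),
        mtf=df["mtf"].to_numpy(),
        frequencies_cpum=df["frequency_cpum"].to_numpy() if "frequency_cpum" in df.columns else None,
        ci95=ci,
    )


def write_stripe_series(series: StripeSeries, tiff_path, csv_path) -> None:
    """Stack as multi-page TIFF plus a sidecar CSV of per-page frequencies."""
    _write_tiff(
        tiff_path,
        series.images.astype(np.float32),
        {"pixel_size_um": series.pixel_size_um, "modulation_axis": series.modulation_axis},
    )
    pd.DataFrame({"page": np.arange(series.images.shape[0]), "frequency_cpum": series.frequencies_cpum}).to_csv(
        csv_path, index=False, float_format="%.17g"
    )


def read_stripe_series(tiff_path, csv_path) -> StripeSeries:
    arr, meta = _read_tiff(tiff_path)
    try:
        freqs = pd.read_csv(csv_path, float_precision="round_trip")["frequency_cpum"].to_numpy()
    except (KeyError, pd.errors.ParserError, OSError) as exc:
        raise FileFormatError(f"cannot read frequency sidecar {csv_path}: {exc}") from exc
    return StripeSeries(
        arr.astype(np.float64),
        freqs,
        float(meta.get("pixel_size_um", 1.0)),
        int(meta.get("modulation_axis", -1)),
    )


def write_metrics_json(metrics: dict, path) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2, default=_json_default))


def read_metrics_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FileFormatError(f"cannot parse JSON metrics from {path}: {exc}") from exc


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
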