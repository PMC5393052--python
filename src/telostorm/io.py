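"""Flat-file interfaces: localization CSV, 16-bit TIFF images, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from telostorm.preprocess import DriftTrajectory, validate_table
from telostorm.simulate import WideFieldImage


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    validate_table(table)
    table.to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_table(table)
    table["frame"] = table["frame"].astype(np.int64)
    return table


def write_widefield(image: WideFieldImage, path: str | Path) -> None:
    pixels = np.clip(np.round(image.pixels), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(
        path,
        pixels,
        metadata={"pixel_size_nm": image.pixel_size_nm, "channel": image.channel},
    )


def read_widefield(
    path: str | Path, pixel_size_nm: float | None = None, channel: str = "probe"
) -> WideFieldImage:
    with tifffile.TiffFile(path) as tf:
        pixels = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if pixel_size_nm is None:
        pixel_size_nm = float(meta.get("pixel_size_nm", 108.0))
    channel = meta.get("channel", channel)
    return WideFieldImage(pixels=pixels, pixel_size_nm=pixel_size_nm, channel=channel)


def write_drift(trajectory: DriftTrajectory, path: str | Path) -> None:
    trajectory.to_frame().to_csv(path, index=False)


def read_drift(path: str | Path, n_fiducials_used: int = 1) -> DriftTrajectory:
    df = pd.read_csv(path)
    return DriftTrajectory(
        dxy_nm=df[["dx_nm", "dy_nm"]].to_numpy(), n_fiducials_used=n_fiducials_used
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
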