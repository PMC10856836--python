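"""File IO for plate images, masks and measurement tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml


def save_rgb_png(path, rgb: np.ndarray) -> None:
    """Write an RGB image (floats in [0, 1]) as 8-bit PNG."""
    arr = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def load_rgb(path) -> np.ndarray:
    """Read an RGB image (PNG/TIFF) as floats in [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return np.asarray(arr, dtype=float)


def save_cf_stack(path, stack: np.ndarray) -> None:
    """Write the F0/Fm/Fs stack as a 3-page 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def load_cf_stack(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def save_thermal(path, thermal: np.ndarray) -> None:
    """Write per-pixel temperatures (degrees C) as a 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(thermal, dtype=np.float32))


def load_thermal(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return np.loadtxt(path, delimiter=",", dtype=float)
    return tifffile.imread(path).astype(float)


def save_mask_png(path, foreground: np.ndarray) -> None:
    """Write a boolean mask as 0/255 8-bit PNG."""
    iio.imwrite(Path(path),
                np.where(np.asarray(foreground, bool), 255, 0).astype(np.uint8))


def load_mask_png(path) -> np.ndarray:
    return iio.imread(Path(path)) > 127


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def load_yaml(path) -> dict:
    with open(Path(path)) as fh:
        return yaml.safe_load(fh)


def save_yaml(path, payload: dict) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
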