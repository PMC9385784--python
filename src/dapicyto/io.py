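"""Reading and writing the pipeline's file formats (TIFF, CSV, JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def save_image(image: np.ndarray, path: str | Path, dtype: str = "uint16") -> None:
    """Write a single-channel image as TIFF.

    ``dtype="uint16"`` rounds and clips to the 16-bit range (the interchange
    format for micrographs); ``dtype="float32"`` preserves sub-integer
    values for lossless round-trips.
    """
    path = Path(path)
    if dtype == "uint16":
        arr = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        arr = np.asarray(image, dtype=np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, arr)


def load_image(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF as float."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    return arr.astype(float)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask as 16-bit TIFF."""
    if mask.max(initial=0) > 65535:
        raise ValueError("more than 65535 labels; cannot store as 16-bit mask")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def load_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def save_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
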