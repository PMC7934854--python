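"""Readers and writers for the package's on-disk formats.

Conventions: 16-bit grayscale TIFF for images, 8-bit PNG (0/255, 255 =
inside) for masks, CSV/TSV with mandatory headers for tables, JSON for
reports.  Pixel coordinates are 0-based (row, col) with the origin at the
top-left.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "read_image",
    "write_image_u16",
    "read_mask",
    "write_mask",
    "read_cone_calls",
    "write_cone_calls",
    "read_de_table",
    "read_term_map",
    "write_json",
    "sha256_file",
]


def read_image(path) -> np.ndarray:
    """Read a grayscale TIFF/PNG as float64; single-channel required."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.all(arr[..., 0] == arr[..., 1]):
            arr = arr[..., 0]
        else:
            raise ValidationError(f"{path} is not a grayscale image")
    return arr.astype(float)


def write_image_u16(path, image: np.ndarray) -> None:
    """Write an intensity grid as 16-bit grayscale TIFF (clipped, rounded)."""
    import tifffile

    arr = np.clip(np.round(np.asarray(image, dtype=float)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), arr)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 PNG mask as boolean (nonzero = inside)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def write_cone_calls(path, cone_set) -> None:
    cone_set.to_dataframe().to_csv(Path(path), index=False)


def read_cone_calls(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = {"row", "col"} - set(df.columns)
    if missing:
        raise ValidationError(f"cone calls file missing columns {sorted(missing)}")
    return df


def read_de_table(path, comparison: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    missing = {"gene", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise ValidationError(f"DE table missing columns {sorted(missing)}")
    if comparison is not None:
        df["comparison"] = comparison
    return df


def read_term_map(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    missing = {"gene", "term"} - set(df.columns)
    if missing:
        raise ValidationError(f"term map missing columns {sorted(missing)}")
    return df


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
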