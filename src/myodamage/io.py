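"""Image and table I/O.

Images are normalized to 8-bit RGB on load: alpha channels are dropped,
16-bit channels are rescaled by integer division by 256, and grayscale or
non-color inputs are rejected. Embedded ICC color profiles are deliberately
ignored — the color models are fitted on the same pixel values that are
classified, so a global color transform cancels out of the analysis.

The per-hip damage table and the dichotomous-outcome table from the study
ship as packaged CSV fixtures (``load_table1`` / ``load_table3``).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .group_stats import DamageTable


def load_image(path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG photograph as an 8-bit RGB array.

    16-bit channels are reduced to 8 bits by integer division by 256;
    RGBA alpha is dropped; palette images are expanded. Grayscale images
    are rejected because stain classification needs color.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            raise ValueError(f"{path}: grayscale image; stain segmentation needs RGB")
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise ValueError(f"{path}: unsupported image shape {arr.shape}")
        arr = arr[:, :, :3]
        if arr.dtype == np.uint16:
            arr = (arr // 256).astype(np.uint8)
        elif arr.dtype != np.uint8:
            raise ValueError(f"{path}: unsupported pixel type {arr.dtype}")
        return arr
    with Image.open(path) as im:
        if im.mode in ("L", "LA", "1", "I", "I;16", "F"):
            raise ValueError(f"{path}: grayscale image; stain segmentation needs RGB")
        if im.mode == "P":
            im = im.convert("RGB")
        if im.mode == "RGBA":
            im = im.convert("RGB")
        if im.mode != "RGB":
            raise ValueError(f"{path}: unsupported image mode {im.mode!r}")
        return np.asarray(im, dtype=np.uint8)


def save_image(image: np.ndarray, path) -> None:
    """Write an 8-bit RGB array as PNG/TIFF/JPEG (by file extension)."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def load_damage_table(path) -> DamageTable:
    """Read a hips × approaches percentage CSV into a validated DamageTable.

    Expects a header row of approach names; a leading ``hip`` column, if
    present, becomes the row index. Non-numeric or out-of-range cells raise
    with the offending row and column named.
    """
    frame = pd.read_csv(path)
    if frame.empty or frame.shape[1] == 0:
        raise ValueError(f"{path}: empty damage table")
    first = frame.columns[0]
    if str(first).strip().lower() in ("hip", "subject", "id"):
        frame = frame.set_index(first)
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}: "
                f"{frame.loc[row, col]!r}"
            )
        frame[col] = coerced
    try:
        return DamageTable(frame)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def _packaged(name: str):
    return resources.files("myodamage.data").joinpath(name)


def load_table1() -> DamageTable:
    """Packaged per-hip gluteus medius damage percentages (5 approaches × 5 hips)."""
    with resources.as_file(_packaged("table1.csv")) as p:
        return load_damage_table(p)


def load_table3() -> pd.DataFrame:
    """Packaged frequencies of released external rotators and transected nerves."""
    with resources.as_file(_packaged("table3.csv")) as p:
        return pd.read_csv(p)
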