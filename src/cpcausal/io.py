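"""File formats: multi-page TIFF image stacks and tabular profile files.

Images travel as 5-page float32 TIFFs (one page per channel, values in
[0, 1]), metadata and profiles as Parquet with CSV fallback. Metadata
columns follow the ``Metadata_*`` convention of high-content screening
profile exports; hidden simulator ground truth uses the ``GT_P_`` prefix.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .scm import CHANNELS

METADATA_IMAGE = [
    "Metadata_Source", "Metadata_Batch", "Metadata_Plate",
    "Metadata_Well", "Metadata_FoV",
]
METADATA_WELL = ["Metadata_Source", "Metadata_Batch", "Metadata_Plate", "Metadata_Well"]
METADATA_TREATMENT = ["Metadata_Compound"]

REQUIRED_METADATA = {
    "image": METADATA_IMAGE + ["Metadata_Compound"],
    "well": METADATA_WELL + ["Metadata_Compound"],
    "treatment": METADATA_TREATMENT,
}


def image_filename(source, batch, plate, well, fov) -> str:
    return f"{source}_{batch}_{plate}_{well}_f{fov}.tiff"


def write_image_stack(image: np.ndarray, path: str | os.PathLike) -> None:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[0] != len(CHANNELS):
        raise ValueError(
            f"expected a ({len(CHANNELS)}, H, W) stack, got shape {image.shape}"
        )
    tifffile.imwrite(path, image)


def read_image_stack(path: str | os.PathLike) -> np.ndarray:
    try:
        arr = tifffile.imread(path)
    except Exception as e:
        raise OSError(f"cannot read image stack at {path}: {e}") from e
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[0] != len(CHANNELS):
        raise ValueError(
            f"{path}: expected {len(CHANNELS)} channel pages, got shape {arr.shape}"
        )
    return arr


def metadata_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(("Metadata_", "GT_"))]


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if not c.startswith(("Metadata_", "GT_"))]


def write_profiles(df: pd.DataFrame, path: str | os.PathLike) -> None:
    path = Path(path)
    # metadata columns first, features after
    cols = metadata_columns(df) + feature_columns(df)
    df = df[cols]
    if path.suffix == ".csv":
        df.to_csv(path, index=False)
    else:
        df.to_parquet(path, index=False)


def read_profiles(path: str | os.PathLike, level: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
    else:
        df = pd.read_parquet(path)
    if level is not None:
        for col in REQUIRED_METADATA[level]:
            if col not in df.columns:
                raise ValueError(f"{path}: missing required metadata column {col}")
    return df
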