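"""Reading and writing binary invasion masks and experiment manifests.

Masks are 8-bit PNG/TIFF images holding only {0, 255}; a manifest is a
CSV with one row per mask file describing the assay layout (well, day,
clone/channel, seeding ratio, replicate, condition), mirroring the
export structure of a time-lapse imaging run.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ("path", "well", "day", "clone", "ratio",
                    "replicate", "condition")


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit 0/255 image."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    iio.imwrite(path, arr)


def read_mask(path) -> np.ndarray:
    """Read a strictly binary mask; any grey value is an error."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    values = np.unique(arr)
    if not np.all(np.isin(values, (0, 255))):
        raise ValueError(
            f"{path}: mask is not binary (pixel values {values.tolist()})")
    return arr == 255


def write_manifest(manifest: pd.DataFrame, path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    manifest.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["well", "day", "clone"])
    if dup.any():
        raise ValueError("manifest has duplicate (well, day, clone) rows")
    if ((df["ratio"] < 0) | (df["ratio"] > 1)).any():
        raise ValueError("seeding ratios must lie in [0, 1]")
    return df


def load_masks(manifest: pd.DataFrame, root=None):
    """Yield (manifest row, mask array) pairs; paths resolve against ``root``."""
    for _, row in manifest.iterrows():
        path = row["path"] if root is None else os.path.join(root, row["path"])
        yield row, read_mask(path)
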