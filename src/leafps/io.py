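"""Readers and writers for the pipeline's file formats.

Greyscale images (PNG/TIFF, 8/16-bit) are normalized to [0, 1] on read by
dividing by the dtype maximum.  Normal maps travel as 3-channel 32-bit
float TIFF plus an albedo TIFF and a validity PNG; label masks as 16-bit
PNG with a frame-index manifest CSV; tables as tidy CSV with a fixed
float format so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .exceptions import ConfigurationError
from .ps import DepthMap, NormalMap

FLOAT_FORMAT = "%.8g"


# ---------------------------------------------------------------- images


def read_grey_image(path) -> np.ndarray:
    """Read a greyscale frame, normalized to [0, 1]."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def write_grey_image(path, img: np.ndarray, bits: int = 16) -> None:
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if bits == 16:
        iio.imwrite(path, (img * 65535).round().astype(np.uint16))
    elif bits == 8:
        iio.imwrite(path, (img * 255).round().astype(np.uint8))
    else:
        raise ConfigurationError("bits must be 8 or 16")


def write_label_mask(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 65535:
        raise ConfigurationError("labels must fit in uint16")
    iio.imwrite(path, labels.astype(np.uint16))


def read_label_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(path)).astype(np.int32)


def write_mask_series(directory, series, prefix: str = "frame") -> Path:
    """Write one 16-bit label PNG per frame plus a manifest CSV; returns
    the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, labels in enumerate(series):
        name = f"{prefix}_{i:05d}.png"
        write_label_mask(directory / name, labels)
        rows.append({"frame": i, "file": name})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_mask_series(manifest_path) -> list[np.ndarray]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path).sort_values("frame")
    return [read_label_mask(manifest_path.parent / f) for f in df.file]


# ----------------------------------------------------------- normal maps


def write_normal_map(stem, nm: NormalMap) -> None:
    """Write <stem>_normals.tif (float32, H x W x 3), <stem>_albedo.tif
    and <stem>_valid.png."""
    stem = Path(stem)
    tifffile.imwrite(
        str(stem) + "_normals.tif", nm.normals.astype(np.float32), photometric="rgb"
    )
    tifffile.imwrite(str(stem) + "_albedo.tif", nm.albedo.astype(np.float32))
    iio.imwrite(str(stem) + "_valid.png", (nm.valid * 255).astype(np.uint8))


def read_normal_map(stem) -> NormalMap:
    stem = Path(stem)
    normals = np.asarray(tifffile.imread(str(stem) + "_normals.tif"), dtype=float)
    albedo = np.asarray(tifffile.imread(str(stem) + "_albedo.tif"), dtype=float)
    valid = np.asarray(iio.imread(str(stem) + "_valid.png")) > 0
    return NormalMap(normals=normals, albedo=albedo, valid=valid)


def write_depth_map(path, dm: DepthMap) -> None:
    tifffile.imwrite(str(path), np.stack([dm.z, dm.valid.astype(float)]).astype(np.float32))


def read_depth_map(path) -> DepthMap:
    arr = np.asarray(tifffile.imread(str(path)), dtype=float)
    return DepthMap(z=arr[0], valid=arr[1] > 0)


def composite_image(nm: NormalMap) -> np.ndarray:
    """Visualization composite: (nx, ny, albedo) mapped to RGB.

    Normal components are remapped from [-1, 1] to [0, 1]; albedo is
    clipped to [0, 1]."""
    r = (nm.nx + 1.0) / 2.0
    g = (nm.ny + 1.0) / 2.0
    b = np.clip(nm.albedo, 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


# ----------------------------------------------------------------- tables


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
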