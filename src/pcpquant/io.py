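"""Reading label masks and channel images, writing result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def read_label_image(path) -> np.ndarray:
    """Read an 8/16/32-bit single-page TIFF or PNG label mask."""
    img = _read(path)
    if img.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got shape {img.shape}")
    if np.issubdtype(img.dtype, np.floating):
        if not np.allclose(img, np.round(img)):
            raise TypeError("label mask must be integer-valued")
        img = img.astype(np.int32)
    return img.astype(np.int32, copy=False)


def read_intensity_image(path) -> np.ndarray:
    img = _read(path)
    if img.ndim != 2:
        raise ValueError(f"channel image must be 2-D, got shape {img.shape}")
    return img.astype(float)


def _read(path) -> np.ndarray:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio
    return np.asarray(iio.imread(path))


def write_tiff(path, image, dtype=None) -> None:
    import tifffile
    arr = np.asarray(image)
    if dtype is not None:
        if np.issubdtype(np.dtype(dtype), np.integer):
            info = np.iinfo(dtype)
            arr = np.clip(np.round(arr), info.min, info.max)
        arr = arr.astype(dtype)
    tifffile.imwrite(path, arr)
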