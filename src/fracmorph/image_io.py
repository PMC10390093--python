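"""Reading and writing masks, grayscale images and feature tables.

Supported formats: NIfTI (.nii / .nii.gz) via nibabel and PNG (8/16-bit) via
Pillow; tables are UTF-8 CSV with a header row.  NIfTI affines are carried
through on write but never interpreted — all geometry is 0-based array
indexing.  All-false masks are accepted here (I/O stays total); analysis
entry points reject them.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .types import BinaryMask, GeometryError, GrayImage

__all__ = [
    "read_mask",
    "read_gray",
    "write_mask",
    "write_gray",
    "write_table",
    "subtract_region",
]

PathLike = Union[str, os.PathLike]


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _load_array(path: PathLike):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[: data.ndim]
        return data, tuple(float(z) for z in zooms)
    if path.suffix.lower() == ".png":
        data = np.asarray(Image.open(path))
        if data.ndim == 3:  # RGB(A): collapse to luminance-ish max channel
            data = data.max(axis=2)
        return data, None
    raise ValueError(f"unsupported format: {path.suffix} (NIfTI or PNG expected)")


def read_mask(path: PathLike) -> BinaryMask:
    """Load a binary mask; any nonzero value is treated as set."""
    data, spacing = _load_array(path)
    if data.ndim not in (2, 3):
        raise GeometryError(f"mask must be 2-D or 3-D, got {data.ndim}-D: {path}")
    mask = BinaryMask(data != 0, spacing=spacing)
    if mask.is_empty:
        warnings.warn(f"mask is all-false: {path}", stacklevel=2)
    return mask


def read_gray(path: PathLike) -> GrayImage:
    """Load a grayscale image at whatever bit depth the file stores."""
    data, spacing = _load_array(path)
    if data.ndim not in (2, 3):
        raise GeometryError(f"image must be 2-D or 3-D, got {data.ndim}-D: {path}")
    return GrayImage(np.asarray(data), spacing=spacing)


def _save_array(data: np.ndarray, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    elif path.suffix.lower() == ".png":
        if data.ndim != 2:
            raise GeometryError("PNG output requires a 2-D array")
        Image.fromarray(data).save(path)
    else:
        raise ValueError(f"unsupported output format: {path.suffix}")


def write_mask(mask: BinaryMask, path: PathLike) -> None:
    """Write a mask as 0/255 PNG or 0/1 uint8 NIfTI (lossless round trip)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        _save_array(mask.data.astype(np.uint8) * 255, path)
    else:
        _save_array(mask.data.astype(np.uint8), path)


def write_gray(image: GrayImage, path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".png":
        data = image.data
        if data.dtype not in (np.uint8, np.uint16):
            data = np.clip(np.round(data), 0, 255).astype(np.uint8)
        _save_array(data, path)
    else:
        _save_array(np.asarray(image.data), path)


def write_table(rows: Union[pd.DataFrame, Sequence[Mapping]], path: PathLike,
                columns: Optional[Sequence[str]] = None) -> None:
    """Write a feature/stats table as CSV with header ('.' decimal, comma)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
        if columns is not None:
            df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False)


def subtract_region(tissue: BinaryMask, tumor: BinaryMask) -> BinaryMask:
    """Voxelwise set difference tissue AND NOT tumor.

    Used to strip the tumor from gray- and white-matter masks so that only
    non-tumorous tissue enters the fractal analysis.
    """
    if tissue.shape != tumor.shape:
        raise GeometryError(
            f"shape mismatch: tissue {tissue.shape} vs tumor {tumor.shape}"
        )
    return BinaryMask(tissue.data & ~tumor.data, spacing=tissue.spacing)
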