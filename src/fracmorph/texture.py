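"""Gray-level co-occurrence matrix (GLCM) texture features.

Region intensities are first quantized to 8-bit, then intensity pairs at a
fixed pixel displacement are tallied into a joint probability matrix p(i, j);
pairs are counted only when *both* endpoints lie inside the region mask.
From p the five classic Haralick scalars are computed: angular second moment
(energy), contrast, inverse difference moment (local homogeneity),
correlation, and entropy (natural log).
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .types import (
    BinaryMask,
    DomainError,
    GLCM,
    GLCMFeatures,
    GrayImage,
)

__all__ = ["quantize_8bit", "compute_glcm", "glcm_features", "region_texture"]

DEFAULT_OFFSET_2D = (0, 1)   # 1 pixel at 0 degrees
DEFAULT_OFFSET_3D = (0, 0, 1)


def quantize_8bit(image: GrayImage, mask: BinaryMask) -> GrayImage:
    """Rescale intensities inside the mask linearly to 0..255 integers
    (min -> 0, max -> 255, rounding half-up); constant regions map to 0.
    Outside the mask the output is 0."""
    if mask.is_empty:
        raise DomainError("quantization requires a nonempty mask")
    if image.shape != mask.shape:
        raise DomainError("image and mask shapes differ")
    vals = image.data[mask.data].astype(float)
    lo, hi = vals.min(), vals.max()
    out = np.zeros(image.shape, dtype=np.uint8)
    if hi > lo:
        scaled = (image.data.astype(float) - lo) * (255.0 / (hi - lo))
        out[mask.data] = np.floor(scaled[mask.data] + 0.5).astype(np.uint8)
    return GrayImage(out, spacing=image.spacing)


def _pair_views(shape: Tuple[int, ...], offset: Sequence[int]):
    """Slicers selecting source and destination voxels of every in-bounds
    pair at the given displacement."""
    src, dst = [], []
    for dim, d in zip(shape, offset):
        d = int(d)
        if abs(d) >= dim:
            raise DomainError("offset exceeds image extent")
        if d >= 0:
            src.append(slice(0, dim - d))
            dst.append(slice(d, dim))
        else:
            src.append(slice(-d, dim))
            dst.append(slice(0, dim + d))
    return tuple(src), tuple(dst)


def compute_glcm(image: GrayImage, mask: BinaryMask,
                 offset: Optional[Sequence[int]] = None,
                 symmetric: bool = False, levels: int = 256) -> GLCM:
    """Tally co-occurring intensity pairs into a normalized L x L matrix.

    Only pairs with both endpoints inside the mask are counted; with
    ``symmetric=True`` each pair is counted in both directions.
    """
    if image.shape != mask.shape:
        raise DomainError("image and mask shapes differ")
    if offset is None:
        offset = DEFAULT_OFFSET_2D if image.ndim == 2 else DEFAULT_OFFSET_3D
    if len(offset) != image.ndim:
        raise DomainError("offset dimensionality must match the image")
    data = image.data
    if np.any(data < 0) or np.any(data > levels - 1):
        raise ValueError(f"image values must lie in [0, {levels - 1}]; quantize first")
    data = data.astype(np.int64)

    src, dst = _pair_views(image.shape, offset)
    valid = mask.data[src] & mask.data[dst]
    if not valid.any():
        raise DomainError("no valid co-occurring pairs inside the mask")
    i = data[src][valid]
    j = data[dst][valid]
    counts = np.bincount(i * levels + j, minlength=levels * levels).reshape(levels, levels)
    if symmetric:
        counts = counts + counts.T
    matrix = counts / counts.sum()
    return GLCM(matrix=matrix, levels=levels, offset=tuple(int(d) for d in offset),
                symmetric=symmetric)


def glcm_features(glcm: GLCM) -> GLCMFeatures:
    """The five Haralick statistics of a normalized co-occurrence matrix.

    Correlation is missing (NaN) when either marginal has zero variance,
    e.g. for a constant region.
    """
    p = glcm.matrix
    L = glcm.levels
    idx = np.arange(L, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")

    asm = float(np.sum(p * p))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz)))

    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    var_i = float(np.sum((ii - mu_i) ** 2 * p))
    var_j = float(np.sum((jj - mu_j) ** 2 * p))
    if var_i <= 0 or var_j <= 0:
        correlation = float("nan")
    else:
        cov = float(np.sum((ii - mu_i) * (jj - mu_j) * p))
        correlation = cov / np.sqrt(var_i * var_j)

    return GLCMFeatures(asm=asm, contrast=contrast, idm=idm,
                        correlation=correlation, entropy=entropy)


def region_texture(image: GrayImage, mask: BinaryMask,
                   offset: Optional[Sequence[int]] = None,
                   symmetric: bool = False, levels: int = 256) -> GLCMFeatures:
    """quantize -> GLCM -> features for one region; an empty region yields a
    missing-value record rather than an error."""
    if mask.is_empty:
        return GLCMFeatures.missing()
    quant = quantize_8bit(image, mask)
    try:
        glcm = compute_glcm(quant, mask, offset=offset, symmetric=symmetric,
                            levels=levels)
    except DomainError:
        # e.g. a 1-pixel region: no co-occurring pairs exist
        return GLCMFeatures.missing()
    return glcm_features(glcm)
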