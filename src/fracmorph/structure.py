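"""Morphological aspect extraction: general structure, boundary, skeleton.

Boundary voxels are the set voxels with at least one unset face-neighbor
(4-connectivity in 2-D, 6-connectivity in 3-D; out-of-array counts as unset),
i.e. the mask minus its face-connected interior.  The skeleton is a
topology-preserving thinning to a one-voxel-wide medial representation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .types import AspectSet, BinaryMask, DomainError

__all__ = ["binarize", "extract_boundary", "extract_skeleton", "extract_all_aspects"]


def binarize(image, threshold: float = 0.0) -> BinaryMask:
    """Threshold a grayscale image: true strictly above ``threshold``."""
    data = np.asarray(getattr(image, "data", image))
    return BinaryMask(data > threshold)


def _face_structure(ndim: int) -> np.ndarray:
    return ndimage.generate_binary_structure(ndim, 1)


def extract_boundary(mask: BinaryMask) -> BinaryMask:
    """Remove the face-connected interior, leaving the one-voxel outline.

    A voxel survives iff it is set and has >= 1 unset face-neighbor; border
    voxels of the array always survive (outside counts as unset).  Single
    voxels and one-voxel-thick structures are their own boundary.
    """
    if mask.is_empty:
        raise DomainError("boundary of an empty mask is undefined")
    interior = ndimage.binary_erosion(
        mask.data, structure=_face_structure(mask.ndim), border_value=0
    )
    return BinaryMask(mask.data & ~interior, spacing=mask.spacing)


def _is_simple_2d(patch: np.ndarray) -> bool:
    """Local simple-point test: deleting the center of the 3x3 patch must
    preserve both the 8-connected foreground and the 4-connected background
    component counts within the patch."""
    without = patch.copy()
    without[1, 1] = False
    eight = np.ones((3, 3), dtype=int)
    fg_before = ndimage.label(patch, structure=eight)[1]
    fg_after = ndimage.label(without, structure=eight)[1]
    if fg_before != fg_after:
        return False
    bg_before = ndimage.label(~patch)[1]
    bg_after = ndimage.label(~without)[1]
    return bg_before == bg_after


def _final_thin_2d(data: np.ndarray) -> np.ndarray:
    """Remove residual 2x2 blocks that iterative thinning can leave behind,
    deleting only simple pixels so topology is untouched."""
    data = data.copy()
    while True:
        blocks = data[:-1, :-1] & data[1:, :-1] & data[:-1, 1:] & data[1:, 1:]
        if not blocks.any():
            return data
        removed = False
        for r, c in zip(*np.nonzero(blocks)):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                i, j = r + dr, c + dc
                if not data[i, j]:
                    continue
                patch = np.zeros((3, 3), dtype=bool)
                r0, r1 = max(i - 1, 0), min(i + 2, data.shape[0])
                c0, c1 = max(j - 1, 0), min(j + 2, data.shape[1])
                patch[r0 - i + 1:r1 - i + 1, c0 - j + 1:c1 - j + 1] = \
                    data[r0:r1, c0:c1]
                if _is_simple_2d(patch):
                    data[i, j] = False
                    removed = True
                    break
        if not removed:
            return data


def extract_skeleton(mask: BinaryMask) -> BinaryMask:
    """Topology-preserving thinning until the region is one voxel wide.

    Uses Zhang–Suen-style thinning in 2-D (with a simple-point final pass
    clearing any residual 2x2 block) and medial-axis thinning in 3-D.
    Connected components are preserved one-to-one; already-thin inputs
    (single voxels, one-pixel lines) pass through unchanged.
    """
    if mask.is_empty:
        raise DomainError("skeleton of an empty mask is undefined")
    skel = np.asarray(skeletonize(mask.data), dtype=bool)
    if skel.ndim == 2:
        skel = _final_thin_2d(skel)
    return BinaryMask(skel, spacing=mask.spacing)


def extract_all_aspects(mask: BinaryMask) -> AspectSet:
    """General structure (the mask itself), boundary and skeleton together."""
    return AspectSet(
        general=BinaryMask(mask.data.copy(), spacing=mask.spacing),
        boundary=extract_boundary(mask),
        skeleton=extract_skeleton(mask),
    )
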