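"""Box-counting fractal dimension estimation.

A structure embedded in a grid obeys the covering law N(S) ~ S^(-D): as the
box side S grows geometrically, the number of boxes N needed to cover the set
shrinks as a power of S.  D is recovered as the negative slope of an ordinary
least-squares fit of log10 N on log10 S.  The counting grid is anchored at
array index 0 with zero-padding to a multiple of the scale; no offset sweep
is performed (``grid_offsets = 1``).
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy import stats

from .structure import extract_all_aspects
from .types import (
    ASPECTS,
    AspectSet,
    BinaryMask,
    BoxCountCurve,
    DomainError,
    FDResult,
)

__all__ = [
    "default_scales",
    "box_count",
    "fit_fd",
    "estimate_fd",
    "fd_of_aspects",
]


def default_scales(mask: BinaryMask, base: int = 2) -> np.ndarray:
    """Geometric box-side schedule base**0, base**1, ... capped at half the
    shortest axis, so the largest scale never collapses to the one-box regime.
    """
    if base not in (2, 3):
        raise ValueError(f"base must be 2 or 3, got {base}")
    if mask.is_empty:
        raise DomainError("cannot build a scale schedule for an empty mask")
    limit = min(mask.shape) // 2
    if limit < base:
        raise DomainError(
            f"mask of shape {mask.shape} is too small for a base-{base} schedule"
        )
    scales = []
    s = 1
    while s <= limit:
        scales.append(s)
        s *= base
    return np.array(scales, dtype=int)


def _count_at_scale(data: np.ndarray, s: int) -> int:
    if s == 1:
        return int(data.sum())
    # pad each axis up to a multiple of s, then block-reduce with any()
    pads = [(0, (-dim) % s) for dim in data.shape]
    padded = np.pad(data, pads, mode="constant", constant_values=False)
    if padded.ndim == 2:
        h, w = padded.shape
        blocks = padded.reshape(h // s, s, w // s, s).any(axis=(1, 3))
    else:
        h, w, d = padded.shape
        blocks = padded.reshape(h // s, s, w // s, s, d // s, s).any(axis=(1, 3, 5))
    return int(blocks.sum())


def box_count(mask: BinaryMask, scales: Optional[Sequence[int]] = None,
              base: int = 2) -> BoxCountCurve:
    """Count occupied boxes of each side in ``scales`` on a fixed grid.

    The grid of s-sided boxes is anchored at index 0; a box is occupied when
    it contains at least one set voxel.  With a geometric schedule the counts
    are automatically nonincreasing because every small box nests inside a
    larger one.
    """
    if mask.is_empty:
        raise DomainError("box counting requires a nonempty mask")
    if scales is None:
        scales = default_scales(mask, base=base)
    scales = np.asarray(list(scales), dtype=int)
    if np.any(scales < 1):
        raise ValueError("scales must be positive integers")
    counts = np.array([_count_at_scale(mask.data, int(s)) for s in scales])
    return BoxCountCurve(scales=scales, counts=counts)


def fit_fd(curve: BoxCountCurve, aspect: Optional[str] = None,
           region: Optional[str] = None) -> FDResult:
    """OLS of log10 N on log10 S; D is the negated slope.

    A perfectly flat curve (all counts equal, e.g. a single voxel) has slope 0
    and, by convention, r^2 = 1: the flat line is an exact fit.
    """
    if len(curve) < 3:
        raise ValueError(f"need >= 3 scales to fit, got {len(curve)}")
    x = curve.log_scales
    y = curve.log_counts
    if np.allclose(y, y[0]):
        return FDResult(D=0.0, intercept=float(y[0]), r_squared=1.0,
                        n_scales=len(curve), aspect=aspect, region=region)
    fit = stats.linregress(x, y)
    return FDResult(
        D=float(-fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        n_scales=len(curve),
        aspect=aspect,
        region=region,
    )


def estimate_fd(mask: BinaryMask, base: int = 2,
                scales: Optional[Sequence[int]] = None,
                aspect: Optional[str] = None,
                region: Optional[str] = None) -> FDResult:
    """Convenience composition: schedule -> box counts -> regression."""
    curve = box_count(mask, scales=scales, base=base)
    return fit_fd(curve, aspect=aspect, region=region)


def fd_of_aspects(aspects: AspectSet, region: Optional[str] = None,
                  base: int = 2) -> List[FDResult]:
    """One FD per morphological aspect (general, boundary, skeleton).

    An empty general mask — e.g. a low-grade tumor without contrast
    enhancement — yields three missing-value records instead of an error, so
    a cohort run never aborts on an absent subregion.
    """
    results: List[FDResult] = []
    for name, m in aspects.as_dict().items():
        if m.is_empty:
            results.append(FDResult.missing(aspect=name, region=region))
        else:
            results.append(estimate_fd(m, base=base, aspect=name, region=region))
    return results


def fd_of_mask(mask: BinaryMask, region: Optional[str] = None,
               base: int = 2) -> List[FDResult]:
    """Aspect extraction followed by per-aspect FD; missing records for an
    empty region."""
    if mask.is_empty:
        return [FDResult.missing(aspect=a, region=region) for a in ASPECTS]
    return fd_of_aspects(extract_all_aspects(mask), region=region, base=base)
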