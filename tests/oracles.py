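"""Independent brute-force oracles used by the test suite.

Each function here is a deliberately naive re-derivation of a quantity the
package computes by a faster route; the oracles share no code with the
implementation paths they check.
"""

import numpy as np


def brute_box_count(data: np.ndarray, s: int) -> int:
    """Exhaustive tiling: walk every s-sided box anchored at index 0."""
    count = 0
    if data.ndim == 2:
        for r0 in range(0, data.shape[0], s):
            for c0 in range(0, data.shape[1], s):
                if data[r0:r0 + s, c0:c0 + s].any():
                    count += 1
    else:
        for r0 in range(0, data.shape[0], s):
            for c0 in range(0, data.shape[1], s):
                for z0 in range(0, data.shape[2], s):
                    if data[r0:r0 + s, c0:c0 + s, z0:z0 + s].any():
                        count += 1
    return count


def brute_boundary(data: np.ndarray) -> np.ndarray:
    """Per-voxel face-neighbor scan; outside the array counts as unset."""
    out = np.zeros_like(data)
    it = np.ndindex(*data.shape)
    for idx in it:
        if not data[idx]:
            continue
        on_edge = False
        for axis in range(data.ndim):
            for d in (-1, 1):
                nb = list(idx)
                nb[axis] += d
                if not (0 <= nb[axis] < data.shape[axis]):
                    on_edge = True
                elif not data[tuple(nb)]:
                    on_edge = True
        out[idx] = on_edge
    return out


def brute_glcm(image: np.ndarray, mask: np.ndarray, offset, levels: int,
               symmetric: bool = False) -> np.ndarray:
    """Pixel-by-pixel pair enumeration."""
    counts = np.zeros((levels, levels), dtype=float)
    dr = offset
    for idx in np.ndindex(*image.shape):
        dst = tuple(i + d for i, d in zip(idx, dr))
        if not all(0 <= v < s for v, s in zip(dst, image.shape)):
            continue
        if mask[idx] and mask[dst]:
            counts[image[idx], image[dst]] += 1
            if symmetric:
                counts[image[dst], image[idx]] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg from the definition: sort, scale by m/rank, then
    enforce monotonicity from the largest p down."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def brute_auc(scores, labels) -> float:
    """All-pairs probability: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
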