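"""Synthetic fixtures and cohorts for validating the fractal/texture pipeline.

Two families of generators:

* **Reference fractals** with known analytic dimensions (Sierpinski carpet
  log8/log3, Sierpinski triangle log3/log2, filled square 2, line 1,
  point 0), constructed so that box counts on the aligned geometric schedule
  equal the self-similar counts *exactly*.

* **Tumor-like cohorts** contrasting a well-circumscribed, compact phenotype
  (low-grade-like) against a larger, rough-edged, branched phenotype
  (high-grade-like).  A tumor mask is a radially perturbed disc — the radius
  profile is a sum of random-phase sinusoids whose amplitude controls
  boundary roughness — with optional random-walk branch protrusions grown
  from boundary points.  Each subject carries the five study regions (whole
  tumor, enhanced tumor, edema, non-tumorous GM and WM) plus textured
  grayscale images whose co-occurrence contrast is group-dependent in the
  enhanced region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .image_io import subtract_region
from .types import BinaryMask, DomainError, GrayImage, REGIONS

__all__ = [
    "ShapeSpec",
    "Subject",
    "SyntheticCohort",
    "gen_reference_fractal",
    "gen_tumor_mask",
    "gen_textured_region",
    "gen_cohort",
    "default_effect",
    "null_effect",
]

MAX_GRID_SIDE = 8192
DEFAULT_CANVAS = 256

REFERENCE_KINDS = ("sierpinski_triangle", "sierpinski_carpet", "filled_square",
                   "line", "point", "disc")


class GenerationError(RuntimeError):
    """Shape parameters produced an unusable (e.g. empty) mask."""


@dataclass
class ShapeSpec:
    """Declarative description of a synthetic shape.

    ``depth_or_size`` is the iteration depth for the iterated fractals
    (carpet grid side 3**depth, triangle 2**depth) and the canvas side for
    everything else.  ``params`` carries the tumor-shape knobs:
    base_radius (px), roughness_amplitude in [0, 1], roughness_frequency
    (number of harmonics, >= 1), n_branches, branch_length (px).
    """

    kind: str
    depth_or_size: int
    params: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_or_size < 1:
            raise ValueError("depth_or_size must be >= 1")
        amp = self.params.get("roughness_amplitude", 0.0)
        if not (0.0 <= amp <= 1.0):
            raise ValueError("roughness_amplitude must lie in [0, 1]")
        freq = self.params.get("roughness_frequency", 1)
        if freq < 1:
            raise ValueError("roughness_frequency must be >= 1")
        for key in ("base_radius", "branch_length"):
            if key in self.params and self.params[key] <= 0:
                raise ValueError(f"{key} must be positive")
        if self.params.get("n_branches", 0) < 0:
            raise ValueError("n_branches must be >= 0")


@dataclass
class Subject:
    subject_id: str
    label: str  # "LGG" or "HGG"
    masks: Dict[str, BinaryMask]
    images: Dict[str, GrayImage]


@dataclass
class SyntheticCohort:
    subjects: List[Subject]
    generator_params: Dict
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)

    def labels(self) -> List[str]:
        return [s.label for s in self.subjects]


# ---------------------------------------------------------------------------
# reference fractals
# ---------------------------------------------------------------------------

def _sierpinski_carpet(depth: int) -> np.ndarray:
    side = 3 ** depth
    idx = np.arange(side)
    keep = np.ones(side, dtype=bool)
    # digit-wise: a coordinate is "central" at level k when its k-th base-3
    # digit equals 1; a pixel is removed iff some level has both digits == 1
    digits = []
    for k in range(depth):
        digits.append((idx // 3 ** k) % 3 == 1)
    mask = np.ones((side, side), dtype=bool)
    for d in digits:
        mask &= ~np.logical_and.outer(d, d)
    return mask


def _sierpinski_triangle(depth: int) -> np.ndarray:
    side = 2 ** depth
    idx = np.arange(side)
    # Pascal-mod-2 construction: pixel (i, j) set iff i AND j == 0, which is
    # exactly self-similar on the power-of-two grid
    return (idx[:, None] & idx[None, :]) == 0


def gen_reference_fractal(spec: ShapeSpec) -> BinaryMask:
    """Deterministic validation shapes with analytically known dimensions."""
    kind = spec.kind
    if kind not in REFERENCE_KINDS:
        raise ValueError(f"not a reference kind: {kind}")

    if kind == "sierpinski_carpet":
        side = 3 ** spec.depth_or_size
        if side > MAX_GRID_SIDE:
            raise GenerationError(f"grid side {side} exceeds {MAX_GRID_SIDE}")
        return BinaryMask(_sierpinski_carpet(spec.depth_or_size))
    if kind == "sierpinski_triangle":
        side = 2 ** spec.depth_or_size
        if side > MAX_GRID_SIDE:
            raise GenerationError(f"grid side {side} exceeds {MAX_GRID_SIDE}")
        return BinaryMask(_sierpinski_triangle(spec.depth_or_size))

    size = spec.depth_or_size
    if size > MAX_GRID_SIDE:
        raise GenerationError(f"grid side {size} exceeds {MAX_GRID_SIDE}")
    if kind == "filled_square":
        return BinaryMask(np.ones((size, size), dtype=bool))
    if kind == "line":
        canvas = np.zeros((size, size), dtype=bool)
        canvas[size // 2, :] = True
        return BinaryMask(canvas)
    if kind == "point":
        canvas = np.zeros((size, size), dtype=bool)
        canvas[size // 2, size // 2] = True
        return BinaryMask(canvas)
    # disc
    radius = spec.params.get("base_radius", size // 4)
    canvas = np.zeros((size, size), dtype=bool)
    rr, cc = draw_disk((size / 2, size / 2), radius, shape=canvas.shape)
    canvas[rr, cc] = True
    return BinaryMask(canvas)


# ---------------------------------------------------------------------------
# tumor-like masks
# ---------------------------------------------------------------------------

def _radial_profile(rng: np.random.Generator, theta: np.ndarray,
                    amplitude: float, n_harmonics: int) -> np.ndarray:
    """Normalized sum of random-phase sinusoids; peak magnitude == amplitude."""
    if amplitude == 0 or n_harmonics < 1:
        return np.zeros_like(theta)
    # skip the k=1 harmonic: it mostly translates the shape
    ks = np.arange(2, 2 + n_harmonics)
    amps = rng.uniform(0.3, 1.0, size=len(ks))
    phases = rng.uniform(0, 2 * np.pi, size=len(ks))
    p = np.zeros_like(theta)
    for k, a, ph in zip(ks, amps, phases):
        p += a * np.sin(k * theta + ph)
    peak = np.max(np.abs(p))
    if peak > 0:
        p = p / peak
    return amplitude * p


def _grow_branch(canvas: np.ndarray, rng: np.random.Generator,
                 start: np.ndarray, direction: np.ndarray,
                 length: int, width: int = 2) -> None:
    pos = start.astype(float)
    ang = math.atan2(direction[0], direction[1])
    for _ in range(int(length)):
        ang += rng.normal(0.0, 0.35)
        pos += np.array([math.sin(ang), math.cos(ang)])
        r = int(round(pos[0]))
        c = int(round(pos[1]))
        if not (0 <= r < canvas.shape[0] and 0 <= c < canvas.shape[1]):
            break
        rr, cc = draw_disk((r, c), width, shape=canvas.shape)
        canvas[rr, cc] = True


def gen_tumor_mask(spec: ShapeSpec,
                   center: Optional[tuple] = None) -> BinaryMask:
    """A connected tumor-like blob on a square canvas.

    With zero roughness and no branches the mask is a smooth disc; raising
    ``roughness_amplitude`` perturbs the boundary radially, and branches grow
    outward as thick random walks from boundary points — the circumscribed
    vs. irregular/infiltrative morphological contrast.
    """
    if spec.kind != "tumor":
        raise ValueError("gen_tumor_mask requires kind='tumor'")
    size = spec.depth_or_size
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    radius = float(p.get("base_radius", size // 6))
    amplitude = float(p.get("roughness_amplitude", 0.0))
    n_harmonics = int(p.get("roughness_frequency", 8))
    n_branches = int(p.get("n_branches", 0))
    branch_length = float(p.get("branch_length", radius * 0.75))

    if center is None:
        center = (size / 2.0, size / 2.0)
    cy, cx = center

    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    profile = _radial_profile(rng, theta, amplitude, n_harmonics)
    # cap relative perturbation at 0.85 so the radius stays positive
    r = radius * (1.0 + 0.85 * profile)
    r = np.clip(r, 2.0, None)

    canvas = np.zeros((size, size), dtype=bool)
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    rr, cc = draw_polygon(rows, cols, shape=canvas.shape)
    canvas[rr, cc] = True

    for _ in range(n_branches):
        t = rng.uniform(0, 2 * np.pi)
        # boundary point at angle t (interpolated radius)
        rt = np.interp(t, theta, r, period=2 * np.pi)
        start = np.array([cy + rt * math.sin(t), cx + rt * math.cos(t)])
        direction = np.array([math.sin(t), math.cos(t)])
        _grow_branch(canvas, rng, start, direction, branch_length)

    if not canvas.any():
        raise GenerationError("tumor parameters produced an empty mask")

    # keep the component containing the core so the result is connected
    labels, n = ndimage.label(canvas)
    if n > 1:
        core = labels[int(round(cy)), int(round(cx))]
        if core == 0:
            sizes = ndimage.sum_labels(canvas, labels, index=np.arange(1, n + 1))
            core = int(np.argmax(sizes)) + 1
        canvas = labels == core
    return BinaryMask(canvas)


# ---------------------------------------------------------------------------
# textured interiors
# ---------------------------------------------------------------------------

def gen_textured_region(mask: BinaryMask, contrast_level: float,
                        noise_sd: float, seed: int) -> GrayImage:
    """Grayscale intensities supported on the mask, zero outside.

    ``contrast_level`` both scales the amplitude of a spatially structured
    (smoothed-noise) pattern and sharpens its spatial scale, so co-occurrence
    contrast and entropy grow monotonically with it even after per-region
    8-bit renormalization.  ``noise_sd`` adds unstructured pixel noise.
    At contrast_level = noise_sd = 0 the region is perfectly flat.
    """
    if contrast_level < 0 or noise_sd < 0:
        raise ValueError("contrast_level and noise_sd must be >= 0")
    if mask.is_empty:
        raise DomainError("textured region requires a nonempty mask")
    rng = np.random.default_rng(seed)
    out = np.zeros(mask.shape, dtype=float)
    base = 128.0
    field_vals = np.full(mask.shape, base)
    if contrast_level > 0:
        sigma = max(0.5, 3.0 / (1.0 + contrast_level))
        pattern = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma)
        sd = pattern.std()
        if sd > 0:
            pattern /= sd
        field_vals = field_vals + 12.0 * contrast_level * pattern
    if noise_sd > 0:
        field_vals = field_vals + noise_sd * rng.standard_normal(mask.shape)
    out[mask.data] = field_vals[mask.data]
    return GrayImage(out)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def default_effect() -> Dict:
    """Group-level shape/texture distributions: a compact, smooth,
    well-circumscribed low-grade-like phenotype against a larger, rougher,
    branched high-grade-like phenotype with a more heterogeneous enhancing
    core."""
    return {
        "LGG": {
            "radius_mean": 30.0, "radius_sd": 4.0,
            "roughness_mean": 0.08, "roughness_sd": 0.04,
            "roughness_frequency": 6,
            "branches_mean": 0.3, "branch_length": 12.0,
            "enhanced_fraction": 0.45,
            "enhanced_contrast": 0.5,
            "base_contrast": 1.0,
            "noise_sd": 1.0,
        },
        "HGG": {
            "radius_mean": 48.0, "radius_sd": 5.0,
            "roughness_mean": 0.55, "roughness_sd": 0.10,
            "roughness_frequency": 16,
            "branches_mean": 6.0, "branch_length": 30.0,
            "enhanced_fraction": 0.60,
            "enhanced_contrast": 4.0,
            "base_contrast": 1.0,
            "noise_sd": 1.0,
        },
    }


def null_effect() -> Dict:
    """Zero group separation: both labels drawn from the LGG distribution."""
    eff = default_effect()
    eff["HGG"] = dict(eff["LGG"])
    return eff


def _validate_effect(effect: Dict) -> None:
    for label in ("LGG", "HGG"):
        if label not in effect:
            raise ValueError(f"effect must define group '{label}'")
        g = effect[label]
        for key in ("radius_sd", "roughness_sd", "noise_sd"):
            if g[key] < 0:
                raise ValueError(f"{label}.{key} must be >= 0")
        if g["radius_mean"] <= 0 or g["branch_length"] <= 0:
            raise ValueError("length parameters must be positive")


def _subject_rng(master_seed: int, index: int) -> np.random.Generator:
    """Counter-scheme sub-seeding: subject i is reproducible in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    )


def _brain_tissue(canvas: int, rng: np.random.Generator):
    """Plausible GM ribbon + WM core: two nested, slightly perturbed
    ellipses; GM is the band between them."""
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    cy = cx = canvas / 2.0
    theta = np.arctan2(yy - cy, xx - cx)
    wobble_out = 1.0 + 0.04 * np.sin(5 * theta + rng.uniform(0, 2 * np.pi)) \
        + 0.03 * np.sin(9 * theta + rng.uniform(0, 2 * np.pi))
    wobble_in = 1.0 + 0.06 * np.sin(7 * theta + rng.uniform(0, 2 * np.pi)) \
        + 0.04 * np.sin(11 * theta + rng.uniform(0, 2 * np.pi))
    a_out = 0.46 * canvas * rng.uniform(0.95, 1.05)
    b_out = 0.40 * canvas * rng.uniform(0.95, 1.05)
    rho = np.sqrt(((yy - cy) / a_out) ** 2 + ((xx - cx) / b_out) ** 2)
    brain = rho <= wobble_out
    inner = rho <= 0.78 * wobble_in
    gm = brain & ~inner
    wm = inner
    return BinaryMask(gm), BinaryMask(wm)


def _make_subject(index: int, label: str, group: Dict, master_seed: int,
                  canvas: int, with_images: bool) -> Subject:
    rng = _subject_rng(master_seed, index)

    radius = max(8.0, rng.normal(group["radius_mean"], group["radius_sd"]))
    roughness = float(np.clip(
        rng.normal(group["roughness_mean"], group["roughness_sd"]), 0.0, 1.0))
    n_branches = int(rng.poisson(group["branches_mean"]))

    # tumor center jittered off-center but inside the white-matter core
    offset = rng.uniform(-0.12 * canvas, 0.12 * canvas, size=2)
    center = (canvas / 2.0 + offset[0], canvas / 2.0 + offset[1])

    def sub_seed() -> int:
        return int(rng.integers(0, 2 ** 31 - 1))

    whole = gen_tumor_mask(ShapeSpec(
        kind="tumor", depth_or_size=canvas, seed=sub_seed(),
        params={
            "base_radius": radius,
            "roughness_amplitude": roughness,
            "roughness_frequency": group["roughness_frequency"],
            "n_branches": n_branches,
            "branch_length": group["branch_length"],
        }), center=center)

    enhanced_core = gen_tumor_mask(ShapeSpec(
        kind="tumor", depth_or_size=canvas, seed=sub_seed(),
        params={
            "base_radius": max(4.0, group["enhanced_fraction"] * radius),
            "roughness_amplitude": roughness,
            "roughness_frequency": group["roughness_frequency"],
            "n_branches": max(0, n_branches - 1),
            "branch_length": group["branch_length"] * 0.6,
        }), center=center)
    enhanced = BinaryMask(enhanced_core.data & whole.data)
    if enhanced.is_empty:  # degenerate overlap: fall back to the eroded core
        enhanced = BinaryMask(ndimage.binary_erosion(whole.data, iterations=3))

    ring = max(2, int(round(0.25 * radius)))
    core = ndimage.binary_erosion(whole.data, iterations=ring)
    edema = BinaryMask(whole.data & ~core)

    gm_raw, wm_raw = _brain_tissue(canvas, rng)
    gm = subtract_region(gm_raw, whole)
    wm = subtract_region(wm_raw, whole)

    masks = {
        "whole_tumor": whole,
        "enhanced_tumor": enhanced,
        "edema": edema,
        "gm": gm,
        "wm": wm,
    }

    images: Dict[str, GrayImage] = {}
    if with_images:
        for region, m in masks.items():
            level = group["enhanced_contrast"] if region == "enhanced_tumor" \
                else group["base_contrast"]
            if m.is_empty:
                images[region] = GrayImage(np.zeros(m.shape))
            else:
                images[region] = gen_textured_region(
                    m, contrast_level=level, noise_sd=group["noise_sd"],
                    seed=sub_seed())

    sid = f"{label.lower()}_{index:03d}"
    return Subject(subject_id=sid, label=label, masks=masks, images=images)


def gen_cohort(n_lgg: int = 27, n_hgg: int = 15,
               effect: Optional[Dict] = None, seed: int = 0,
               canvas: int = DEFAULT_CANVAS,
               with_images: bool = True) -> SyntheticCohort:
    """Simulate a two-group cohort of segmented subjects.

    Defaults mirror the study design this pipeline targets: 27 low-grade-like
    and 15 high-grade-like subjects, five regions each.  ``with_images=False``
    skips texture synthesis when only shape features are needed.
    """
    if n_lgg < 2 or n_hgg < 2:
        raise ValueError("need at least 2 subjects per group")
    if effect is None:
        effect = default_effect()
    _validate_effect(effect)

    subjects: List[Subject] = []
    labels = ["LGG"] * n_lgg + ["HGG"] * n_hgg
    for i, label in enumerate(labels):
        subjects.append(_make_subject(i, label, effect[label], seed, canvas,
                                      with_images))
    params = {"n_lgg": n_lgg, "n_hgg": n_hgg, "canvas": canvas,
              "effect": effect, "with_images": with_images}
    return SyntheticCohort(subjects=subjects, generator_params=params, seed=seed)
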