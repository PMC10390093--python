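"""Core value types shared across the pipeline.

The substrate of every analysis is a binary region mask (2-D slice or 3-D
volume).  Fractal-dimension estimation produces a box-count curve and a fitted
dimension; texture analysis produces a small co-occurrence feature record.
All containers are thin, validated wrappers over numpy arrays / scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

REGIONS = ("whole_tumor", "enhanced_tumor", "edema", "gm", "wm")
TUMOR_REGIONS = ("whole_tumor", "enhanced_tumor", "edema")
NONTUMOR_REGIONS = ("gm", "wm")
ASPECTS = ("general", "boundary", "skeleton")
TEXTURE_FEATURES = ("asm", "contrast", "idm", "correlation", "entropy")

LABELS = ("LGG", "HGG")


class GeometryError(ValueError):
    """Shape/dimension disagreement between paired arrays."""


class DomainError(ValueError):
    """Operation applied outside its domain (e.g. empty mask)."""


@dataclass
class BinaryMask:
    """A 2-D or 3-D boolean region mask with optional voxel spacing (mm).

    Indexing is plain 0-based array indexing; no world-coordinate math is
    performed anywhere in the package.
    """

    data: np.ndarray
    spacing: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise GeometryError(
                f"mask must be 2-D or 3-D, got {self.data.ndim}-D"
            )
        if self.data.dtype != bool:
            self.data = self.data != 0
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != self.data.ndim:
                raise GeometryError("spacing length must match dimensionality")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_set(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.data.any())


@dataclass
class GrayImage:
    """A scalar intensity image sharing the mask's shape semantics."""

    data: np.ndarray
    spacing: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise GeometryError(
                f"image must be 2-D or 3-D, got {self.data.ndim}-D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class AspectSet:
    """The three morphological aspects of a region: full mask, one-voxel
    outline, and thinned medial skeleton."""

    general: BinaryMask
    boundary: BinaryMask
    skeleton: BinaryMask

    def as_dict(self) -> dict:
        return {
            "general": self.general,
            "boundary": self.boundary,
            "skeleton": self.skeleton,
        }


@dataclass
class BoxCountCurve:
    """Paired box sides S and occupied-box counts N(S), grid anchored at
    array index 0, plus the log10 transforms the regression consumes."""

    scales: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.scales.shape != self.counts.shape:
            raise ValueError("scales and counts must have equal length")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if np.any(self.counts < 1):
            raise ValueError("counts must be >= 1 (empty masks are rejected upstream)")
        if np.any(np.diff(self.counts) > 0):
            raise ValueError("counts must be nonincreasing in scale")

    @property
    def log_scales(self) -> np.ndarray:
        return np.log10(self.scales.astype(float))

    @property
    def log_counts(self) -> np.ndarray:
        return np.log10(self.counts.astype(float))

    def __len__(self) -> int:
        return len(self.scales)


@dataclass
class FDResult:
    """A fitted box-counting dimension with its regression diagnostics."""

    D: float
    intercept: float
    r_squared: float
    n_scales: int
    aspect: Optional[str] = None
    region: Optional[str] = None

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.D)

    @classmethod
    def missing(cls, aspect: Optional[str] = None, region: Optional[str] = None) -> "FDResult":
        return cls(D=float("nan"), intercept=float("nan"), r_squared=float("nan"),
                   n_scales=0, aspect=aspect, region=region)


@dataclass
class GLCM:
    """Normalized gray-level co-occurrence matrix: joint probability p(i, j)
    of intensity pairs at a fixed displacement, levels x levels."""

    matrix: np.ndarray
    levels: int
    offset: tuple
    symmetric: bool

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.levels, self.levels):
            raise ValueError("GLCM must be levels x levels")
        if np.any(self.matrix < 0):
            raise ValueError("GLCM entries must be nonnegative")
        total = self.matrix.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"GLCM must sum to 1, got {total}")


@dataclass
class GLCMFeatures:
    """The five Haralick scalars used for region comparison.  Correlation is
    NaN (missing) for zero-variance images rather than an arbitrary value."""

    asm: float
    contrast: float
    idm: float
    correlation: float
    entropy: float

    def as_dict(self) -> dict:
        return {
            "asm": self.asm,
            "contrast": self.contrast,
            "idm": self.idm,
            "correlation": self.correlation,
            "entropy": self.entropy,
        }

    @classmethod
    def missing(cls) -> "GLCMFeatures":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan)


def fd_feature_name(region: str, aspect: str) -> str:
    return f"fd_{region}_{aspect}"


def texture_feature_name(region: str, feature: str) -> str:
    return f"tex_{region}_{feature}"


def fd_feature_names() -> list:
    """The 15 fractal features: 3 aspects x 5 regions."""
    return [fd_feature_name(r, a) for r in REGIONS for a in ASPECTS]


def texture_feature_names() -> list:
    """The 25 texture features: 5 Haralick scalars x 5 regions."""
    return [texture_feature_name(r, f) for r in REGIONS for f in TEXTURE_FEATURES]
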