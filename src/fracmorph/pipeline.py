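"""End-to-end study orchestration.

A cohort (real segmentations or a synthetic one) is turned into a feature
table — 15 fractal-dimension features (3 morphological aspects x 5 regions)
and 25 co-occurrence texture features (5 Haralick scalars x 5 regions) per
subject — which then feeds the two-group statistics and the cross-validated
SVM classification.  Everything is deterministic given the configuration
seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classification import ClassificationReport, select_best_kernel
from .fractal import fd_of_mask
from .group_stats import StatResult, results_to_frame, summarize_cohort
from .synthetic import SyntheticCohort, Subject, default_effect, gen_cohort, null_effect
from .texture import region_texture
from .types import (
    ASPECTS,
    REGIONS,
    TEXTURE_FEATURES,
    fd_feature_name,
    fd_feature_names,
    texture_feature_name,
    texture_feature_names,
)

__all__ = ["StudyConfig", "StudyReport", "extract_subject_features",
           "cohort_feature_table", "run_study"]


@dataclass
class StudyConfig:
    """Declarative study configuration; every methodological choice that the
    analysis leaves open is a named field with its documented default."""

    n_lgg: int = 27
    n_hgg: int = 15
    seed: int = 0
    canvas: int = 256
    effect: str = "default"          # "default" | "null"
    scales_base: int = 2             # box-side schedule base
    glcm_offset: Optional[tuple] = None  # None -> 1 px at 0 degrees
    glcm_symmetric: bool = False
    cv_mode: str = "shuffle"         # "shuffle" (5x stratified 70/30) | "kfold"
    n_folds: int = 5
    with_texture: bool = True
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if self.n_lgg < 2 or self.n_hgg < 2:
            raise ValueError("n_lgg and n_hgg must be >= 2")
        if self.effect not in ("default", "null"):
            raise ValueError(f"unknown effect preset: {self.effect!r}")
        if self.scales_base not in (2, 3):
            raise ValueError("scales_base must be 2 or 3")
        if self.cv_mode not in ("shuffle", "kfold"):
            raise ValueError(f"unknown cv_mode: {self.cv_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class StudyReport:
    config: Dict
    features: pd.DataFrame
    stats_fd: List[StatResult]
    stats_texture: List[StatResult]
    classification: List[ClassificationReport]

    def classification_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {k: v for k, v in r.as_dict().items() if k != "folds"}
            for r in self.classification
        ])


def extract_subject_features(masks: Dict, images: Optional[Dict] = None,
                             scales_base: int = 2,
                             glcm_offset: Optional[Sequence[int]] = None,
                             glcm_symmetric: bool = False,
                             with_texture: bool = True) -> Dict[str, float]:
    """One feature row: 15 FD values (+25 texture values when images are
    supplied).  Empty regions produce NaN entries rather than failures."""
    row: Dict[str, float] = {}
    for region in REGIONS:
        mask = masks[region]
        for res in fd_of_mask(mask, region=region, base=scales_base):
            row[fd_feature_name(region, res.aspect)] = res.D
        if with_texture and images is not None:
            feats = region_texture(images[region], mask, offset=glcm_offset,
                                   symmetric=glcm_symmetric)
            for name, val in feats.as_dict().items():
                row[texture_feature_name(region, name)] = val
    return row


def cohort_feature_table(cohort: SyntheticCohort, scales_base: int = 2,
                         glcm_offset: Optional[Sequence[int]] = None,
                         glcm_symmetric: bool = False,
                         with_texture: bool = True) -> pd.DataFrame:
    """Feature extraction over every subject; rows are labeled LGG/HGG."""
    rows = []
    for subj in cohort.subjects:
        if all(m.is_empty for m in subj.masks.values()):
            continue  # nothing to measure for this subject
        row = {"subject_id": subj.subject_id, "label": subj.label}
        row.update(extract_subject_features(
            subj.masks, subj.images if with_texture else None,
            scales_base=scales_base, glcm_offset=glcm_offset,
            glcm_symmetric=glcm_symmetric,
            with_texture=with_texture and bool(subj.images)))
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyReport:
    """Simulate (or load) a cohort, extract features, compare groups with
    FDR within each feature family, and classify grade from each FD
    region-aspect feature and from the per-region texture-feature groups."""
    config.validate()
    effect = default_effect() if config.effect == "default" else null_effect()
    cohort = gen_cohort(config.n_lgg, config.n_hgg, effect=effect,
                        seed=config.seed, canvas=config.canvas,
                        with_images=config.with_texture)
    features = cohort_feature_table(
        cohort, scales_base=config.scales_base,
        glcm_offset=config.glcm_offset, glcm_symmetric=config.glcm_symmetric,
        with_texture=config.with_texture)

    fd_cols = [c for c in fd_feature_names() if c in features.columns]
    tex_cols = [c for c in texture_feature_names() if c in features.columns]
    stats_fd = summarize_cohort(features, feature_cols=fd_cols)
    stats_tex = summarize_cohort(features, feature_cols=tex_cols)

    classification: List[ClassificationReport] = []
    labels = features["label"].to_numpy()
    # one report per single FD feature (region x aspect), as in the FD tables
    for col in fd_cols:
        x = features[col].to_numpy()
        if np.sum(np.isfinite(x)) < 8:
            continue
        classification.append(select_best_kernel(
            x[:, None], labels, seed=config.seed, n_folds=config.n_folds,
            cv_mode=config.cv_mode, feature_set=col))
    # one report per region using all five texture features together
    for region in REGIONS:
        cols = [texture_feature_name(region, f) for f in TEXTURE_FEATURES]
        cols = [c for c in cols if c in features.columns]
        if not cols:
            continue
        X = features[cols].to_numpy()
        if np.sum(np.all(np.isfinite(X), axis=1)) < 8:
            continue
        classification.append(select_best_kernel(
            X, labels, seed=config.seed, n_folds=config.n_folds,
            cv_mode=config.cv_mode, feature_set=f"tex_{region}"))

    config_snapshot = {"fracmorph_version": __version__, **asdict(config)}
    config_snapshot.pop("out_dir", None)  # provenance, not method
    report = StudyReport(
        config=config_snapshot,
        features=features,
        stats_fd=stats_fd,
        stats_texture=stats_tex,
        classification=classification,
    )
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: StudyReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.features.to_csv(out / "features.csv", index=False)
    results_to_frame(report.stats_fd).to_csv(out / "stats_fd.csv", index=False)
    results_to_frame(report.stats_texture).to_csv(out / "stats_texture.csv",
                                                  index=False)
    with open(out / "classification.json", "w") as fh:
        json.dump({"config": report.config,
                   "reports": [r.as_dict() for r in report.classification]},
                  fh, indent=2)
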