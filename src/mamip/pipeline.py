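"""End-to-end orchestration: volumes -> crop -> MA-MIPs -> features -> CV.

This module wires the stages together for cohort-level runs: bone-window
CT projections propose the head-and-neck box, the registered PET is
cropped, multi-angle MIPs are extracted and encoded, views are fused per
patient, and the fused features enter the nested cross-validated Cox
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deep_features import FeatureMatrix, extract_mamip_features
from .fusion import (
    STAT_FUSIONS,
    apply_autoencoder_fusion,
    apply_ica_fusion,
    fit_autoencoder_fusion,
    fit_ica_fusion,
    fuse_statistical,
)
from .phantom import Cohort
from .projections import PrepConfig, generate_ma_mips
from .region_crop import combine_boxes_3d, crop, map_box_to_volume, plane_mip, propose_boxes_heuristic
from .survival import CohortFeatures, CVConfig, CVResult, nested_cv
from .volume_io import ImageVolume, clip_hu

__all__ = ["FeatureConfig", "extract_patient_features", "cohort_feature_matrices",
           "fuse_cohort", "run_cohort_analysis"]


@dataclass
class FeatureConfig:
    """Feature-extraction settings for cohort runs.

    The 5-degree step (72 views) is the full-resolution setting; coarser
    steps that still divide 360 trade angular resolution for speed. For
    cohort analyses the fixed intensity window keeps uptake comparable
    across patients (per-image min-max would discard absolute intensity).
    """

    step_deg: float = 5.0
    backbone: str = "small"
    pooling: str = "avg"
    prep: PrepConfig = field(
        default_factory=lambda: PrepConfig(normalization="fixed", fixed_window=(0.0, 12.0))
    )


def extract_patient_features(
    ct: ImageVolume, pet: ImageVolume, config: FeatureConfig
) -> FeatureMatrix:
    """Full single-patient feature path from raw volumes.

    Bone-window CT MIPs -> heuristic 2D boxes -> combined 3D box mapped
    onto the PET grid -> crop -> MA-MIP stack -> pooled encoder features.
    """
    bone = clip_hu(ct)
    cor, sag = propose_boxes_heuristic(plane_mip(bone, "coronal"), plane_mip(bone, "sagittal"))
    box_ct = combine_boxes_3d(cor, sag, ct.shape)
    box_pet = map_box_to_volume(box_ct, ct, pet)
    cropped = crop(pet, box_pet)
    stack = generate_ma_mips(cropped, config.step_deg)
    return extract_mamip_features(stack, config.backbone, config.pooling, config.prep)


def cohort_feature_matrices(cohort: Cohort, config: FeatureConfig) -> list[FeatureMatrix]:
    return [
        extract_patient_features(ct, pet, config)
        for ct, pet in zip(cohort.ct, cohort.pet)
    ]


def fuse_cohort(
    matrices: list[FeatureMatrix],
    fusion: str,
    patient_ids: list[str],
    seed: int = 0,
    latent_dim: int | None = None,
) -> CohortFeatures:
    """Fuse per-patient view matrices into a cohort feature table.

    Statistical fusions are stateless per patient. The learned fusions
    (``ica``, ``autoencoder``) here fit on the *whole* given cohort — use
    this only for exploratory tables; fold-safe evaluation fits them per
    training fold inside the cross-validation.
    """
    if fusion in STAT_FUSIONS:
        rows = [fuse_statistical(m, fusion).values for m in matrices]
    elif fusion == "ica":
        model = fit_ica_fusion(matrices, seed)
        rows = [apply_ica_fusion(model, m).values for m in matrices]
    elif fusion == "autoencoder":
        v, c = matrices[0].values.shape
        ld = latent_dim or min(256, v * c - 1)
        model = fit_autoencoder_fusion(matrices, latent_dim=ld, seed=seed)
        rows = [apply_autoencoder_fusion(model, m).values for m in matrices]
    else:
        raise ValueError(f"unknown fusion {fusion!r}")
    mat = np.vstack(rows)
    names = [f"{fusion}_{j}" for j in range(mat.shape[1])]
    return CohortFeatures(mat, names, list(patient_ids))


def run_cohort_analysis(
    cohort: Cohort,
    feature_config: FeatureConfig | None = None,
    fusion: str = "cw_mean",
    cv_config: CVConfig | None = None,
) -> tuple[CVResult, CohortFeatures]:
    """Image volumes to cross-validated c-indices for a whole cohort."""
    feature_config = feature_config or FeatureConfig()
    cv_config = cv_config or CVConfig()
    matrices = cohort_feature_matrices(cohort, feature_config)
    ids = [r.patient_id for r in cohort.records]
    features = fuse_cohort(matrices, fusion, ids, seed=cv_config.seed)
    result = nested_cv(features, cohort.records, cv_config)
    return result, features
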