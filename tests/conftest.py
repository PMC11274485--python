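"""Shared fixtures: phantom cohorts and their extracted feature tables.

The two n=200 cohorts (informative beta=1.5 and null beta=0) and their
feature matrices are expensive, so they are built once per session and
shared by the phantom, pipeline and acceptance tests.
"""

import dataclasses

import numpy as np
import pytest

from mamip.phantom import PhantomSpec, make_cohort
from mamip.pipeline import FeatureConfig, cohort_feature_matrices, fuse_cohort
from mamip.survival import CVConfig, nested_cv

#: Reduced-size analysis settings used for cohort-level runs in the suite:
#: 30-degree steps (12 views) and the small encoder keep the end-to-end
#: paths CPU-friendly while exercising every stage.
COHORT_FEATURE_CONFIG = FeatureConfig(step_deg=30.0)
COHORT_CV_CONFIG = dict(n_outer=5, n_repeats=2)


@pytest.fixture(scope="session")
def informative_cohort():
    """n=200 cohort with the default Cox effect (beta=1.5, 20% censoring)."""
    return make_cohort(PhantomSpec(), n=200, seed=7)


@pytest.fixture(scope="session")
def null_cohort():
    """n=200 cohort whose outcomes are independent of the images (beta=0)."""
    spec = dataclasses.replace(PhantomSpec(), beta=0.0)
    return make_cohort(spec, n=200, seed=8)


def _fused_features(cohort):
    mats = cohort_feature_matrices(cohort, COHORT_FEATURE_CONFIG)
    return fuse_cohort(mats, "cw_mean", [r.patient_id for r in cohort.records])


@pytest.fixture(scope="session")
def informative_features(informative_cohort):
    return _fused_features(informative_cohort)


@pytest.fixture(scope="session")
def null_features(null_cohort):
    return _fused_features(null_cohort)


@pytest.fixture(scope="session")
def informative_cv(informative_cohort, informative_features):
    return nested_cv(
        informative_features,
        informative_cohort.records,
        CVConfig(seed=1, **COHORT_CV_CONFIG),
    )


@pytest.fixture(scope="session")
def null_cv(null_cohort, null_features):
    return nested_cv(
        null_features, null_cohort.records, CVConfig(seed=2, **COHORT_CV_CONFIG)
    )
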