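"""Shared fixtures: small synthetic atlases, cohorts and study runs.

Heavy objects (study reports, replicate sweeps) are session-scoped so the
suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from painmvpa.atlas import make_atlas
from painmvpa.confidence import exclusion_curve
from painmvpa.design import make_design
from painmvpa.extraction import build_feature_mask, extract_subject_examples, vectorize_examples
from painmvpa.pipeline import StudyConfig, run_study
from painmvpa.simulate import CohortParams, iter_cohort
from painmvpa.svm import decide_batch, train

SMALL_GRID = (16, 18, 14)
REPLICATE_GRID = (12, 14, 12)
REPLICATE_FRACTIONS = np.arange(0.0, 0.31, 0.05)


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def small_atlas():
    """Reduced grid with the default planted pain-network layout."""
    return make_atlas(grid_shape=SMALL_GRID, voxel_mm=4.0, seed=0)


@pytest.fixture(scope="session")
def clean_small_atlas():
    """Same geometry without artifact voxels (for exact round trips)."""
    return make_atlas(grid_shape=SMALL_GRID, voxel_mm=4.0, seed=0, n_artifact_voxels=0)


@pytest.fixture(scope="session")
def null_atlas():
    """Signal-free atlas: no regions, no artifacts."""
    return make_atlas(grid_shape=REPLICATE_GRID, voxel_mm=4.0, regions=(), seed=0,
                      n_artifact_voxels=0)


@pytest.fixture(scope="session")
def small_report():
    """One complete small-scale study run shared across tests."""
    cfg = StudyConfig(
        grid_shape=SMALL_GRID,
        n_train_test=8,
        n_retest=4,
        n_permutations=50,
        fwhm_mm=0.0,
    )
    return run_study(cfg)


def decode_replicate(seed: int, fractions=REPLICATE_FRACTIONS, n_per_group: int = 4,
                     grid=REPLICATE_GRID):
    """Simulate one train/test cohort pair, decode, return the accuracy curve.

    Returns accuracy (%) at each exclusion fraction, pooled over the test
    group — one independent replicate of the confidence-rejection analysis.
    """
    design = make_design()
    atlas = make_atlas(grid_shape=grid, voxel_mm=4.0, seed=seed)
    params = CohortParams()
    train_examples = []
    for subject in iter_cohort(n_per_group, design, atlas, params, seed=seed * 2 + 1,
                               subject_prefix="tr-"):
        train_examples.extend(extract_subject_examples(subject))
    test_examples = []
    for subject in iter_cohort(n_per_group, design, atlas, params, seed=seed * 2 + 2,
                               subject_prefix="te-"):
        test_examples.extend(extract_subject_examples(subject))
    mask = build_feature_mask(atlas.gray_mask, train_examples, affine=atlas.affine)
    Xtr, ytr, _ = vectorize_examples(train_examples, mask)
    Xte, yte, _ = vectorize_examples(test_examples, mask)
    model = train(Xtr, ytr)
    curve = exclusion_curve(decide_batch(model, Xte), yte, fractions)
    return curve.accuracy


@pytest.fixture(scope="session")
def rejection_replicates():
    """Accuracy-vs-exclusion curves over 50 seeded train/test replicates."""
    return np.array([decode_replicate(seed) for seed in range(50)])
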