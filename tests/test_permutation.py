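import itertools

import numpy as np
import pytest

from painmvpa.extraction import FeatureMask
from painmvpa.permutation import (
    PermutationError,
    PermutationNull,
    build_null,
    flagged_fraction,
    permute_labels,
    significance_map,
)
from painmvpa.svm import LinearModel


def _training_labels(n_subjects=8, per_class=14):
    y = np.tile(np.r_[np.ones(per_class), -np.ones(per_class)].astype(int), n_subjects)
    sids = np.repeat([f"sub-{i:02d}" for i in range(n_subjects)], 2 * per_class).astype(object)
    return y, sids


def test_within_subject_permutations_preserve_class_counts():
    y, sids = _training_labels()
    perms = permute_labels(y, sids, n_permutations=750, seed=0)
    assert perms.shape == (750, 224)
    assert (perms.sum(axis=1) == 0).all()  # 112 painful + 112 nonpainful each
    for sid in np.unique(sids):
        sel = sids == sid
        assert (perms[:, sel].sum(axis=1) == 0).all()


def test_permutation_sequence_reproducible_from_seed():
    y, sids = _training_labels(2)
    p1 = permute_labels(y, sids, 20, seed=42)
    p2 = permute_labels(y, sids, 20, seed=42)
    p3 = permute_labels(y, sids, 20, seed=43)
    assert np.array_equal(p1, p2)
    assert not np.array_equal(p1, p3)


def test_single_subject_permutations_enumerate_within_subject_arrangements():
    y = np.array([1, 1, -1, -1])
    sids = np.array(["s"] * 4, dtype=object)
    perms = permute_labels(y, sids, 200, seed=0)
    allowed = {p for p in itertools.permutations([1, 1, -1, -1])}
    assert len(allowed) == 6
    seen = {tuple(p) for p in perms}
    assert seen <= allowed
    assert len(seen) == 6  # 200 draws hit all 6 arrangements


def test_full_shuffle_mode_breaks_subject_structure():
    y, sids = _training_labels(2, per_class=3)
    perms = permute_labels(y, sids, 500, seed=1, within_subject=False)
    per_subject_sums = perms[:, sids == "sub-00"].sum(axis=1)
    assert (perms.sum(axis=1) == 0).all()
    assert (per_subject_sums != 0).any()  # pooled shuffling unbalances subjects


def test_empty_null_is_allowed_but_unusable():
    X = np.random.default_rng(0).normal(size=(8, 5))
    null = build_null(X, np.empty((0, 8)))
    assert null.n_permutations == 0
    mask = FeatureMask(include=np.ones((5, 1, 1), bool))
    model = LinearModel(weights=np.ones(5), bias=0.0)
    with pytest.raises(PermutationError, match="empty"):
        significance_map(model, null, mask)


def test_null_centers_at_zero_and_true_signal_weight_is_extreme():
    """Relabeling destroys the label-feature association: per-feature null
    weights center at 0, and the weight of a strongly predictive feature
    under correct labels lands beyond the entire null."""
    rng = np.random.default_rng(2)
    n = 40
    y = np.r_[np.ones(n // 2), -np.ones(n // 2)].astype(int)
    X = rng.normal(size=(n, 3))
    X[:, 0] = y * 2.0 + rng.normal(0, 0.1, n)
    sids = np.array(["s"] * n, dtype=object)
    from painmvpa.svm import train

    w_true = train(X, y).weights
    perms = permute_labels(y, sids, 60, seed=0)
    perms = perms[(perms != y).any(axis=1)]  # drop the identity relabeling
    null = build_null(X, perms)
    centers = np.median(null.null_weights, axis=0)
    assert np.abs(centers).max() < 0.1
    assert (null.null_weights[:, 0] < w_true[0]).all()


def test_build_null_deterministic_from_seed():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(16, 6))
    y = np.r_[np.ones(8), -np.ones(8)].astype(int)
    sids = np.repeat(["a", "b"], 8).astype(object)
    perms = permute_labels(y, sids, 50, seed=5)
    n1 = build_null(X, perms)
    n2 = build_null(X, permute_labels(y, sids, 50, seed=5))
    assert np.array_equal(n1.null_weights, n2.null_weights)


def _mask_and_model(n_features, weights):
    mask = FeatureMask(include=np.ones((n_features, 1, 1), bool))
    return mask, LinearModel(weights=np.asarray(weights, float), bias=0.0)


def test_extreme_weight_hits_percentile_100_and_p01_mask():
    rng = np.random.default_rng(4)
    null_w = rng.normal(0, 1, size=(200, 3))
    mask, model = _mask_and_model(3, [10.0, 0.0, -10.0])
    null = PermutationNull(null_weights=null_w, seed=0)
    sig = significance_map(model, null, mask)
    pct = sig.percentile_map.ravel()
    assert pct[0] == 100.0
    assert pct[2] == 0.0
    assert sig.positive_mask_p01.ravel()[0]
    assert sig.negative_mask_p01.ravel()[2]
    assert not sig.positive_mask_p01.ravel()[1]
    assert not sig.negative_mask_p01.ravel()[1]


def test_median_weight_sits_at_percentile_50_in_no_mask():
    null_w = np.linspace(-1, 1, 201)[:, None] * np.ones((1, 1))
    mask, model = _mask_and_model(1, [0.0])
    sig = significance_map(model, PermutationNull(null_w, seed=0), mask)
    assert sig.percentile_map.ravel()[0] == pytest.approx(50.0, abs=0.5)
    for attr in ("positive_mask_p01", "negative_mask_p01",
                 "positive_mask_p10", "negative_mask_p10"):
        assert not getattr(sig, attr).any()


def test_mask_nesting_and_sign_disjointness():
    rng = np.random.default_rng(6)
    null_w = rng.normal(size=(300, 50))
    mask, model = _mask_and_model(50, rng.normal(0, 2, 50))
    sig = significance_map(model, PermutationNull(null_w, seed=0), mask)
    assert not (sig.positive_mask_p01 & ~sig.positive_mask_p10).any()
    assert not (sig.negative_mask_p01 & ~sig.negative_mask_p10).any()
    assert not (sig.positive_mask_p10 & sig.negative_mask_p10).any()
    # enlarging alpha never shrinks the flagged set
    fractions = [flagged_fraction(sig, a) for a in (0.01, 0.05, 0.10, 0.20)]
    assert fractions == sorted(fractions)


def test_feature_mismatch_raises():
    mask, model = _mask_and_model(3, [1.0, 2.0, 3.0])
    null = PermutationNull(null_weights=np.zeros((10, 4)), seed=0)
    with pytest.raises(PermutationError, match="match"):
        significance_map(model, null, mask)
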