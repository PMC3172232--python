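"""Label-permutation null distributions for voxel weights.

To locate the brain regions that drive the decoder, the class labels of the
training examples are randomly permuted (750 times by default) and the SVM
retrained on each relabeling, yielding an empirical per-voxel null
distribution of weights.  The weight map of the correctly labeled model is
then ranked against this null voxel by voxel.

Permutation is within subject by default (each subject's labels are
shuffled among that subject's examples, preserving per-subject class
counts), respecting the exchangeability structure of a grouped design; a
pooled full-shuffle mode is available.

Significance is two-sided and split by weight sign, mirroring directional
red/blue display maps: a voxel enters the positive (pain-predictive) mask
at level ``alpha`` when its add-one permutation p-value
``(1 + #{null >= observed}) / (n_perm + 1)`` is at most ``alpha/2``, and
symmetrically for the negative mask.  The percentile map uses mid-rank
scaling to 0-100.  No multiple-comparison correction is applied — maps are
descriptive, voxelwise uncorrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .extraction import FeatureMask
from .svm import DEFAULT_C, LinearModel, SVMError, precompute_kernel, train_from_kernel

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 750
PERMUTATION_TOL = 1e-6  # solver tolerance for null retrainings


class PermutationError(ValueError):
    pass


@dataclass
class PermutationNull:
    """Null weight distributions: one weight vector per relabeled model."""

    null_weights: np.ndarray      # (n_permutations, n_features)
    seed: int
    c_param: float = DEFAULT_C

    @property
    def n_permutations(self) -> int:
        return self.null_weights.shape[0]


@dataclass
class SignificanceMap:
    """Mid-rank percentile map plus sign-split significance masks.

    ``percentile_map`` is NaN outside the feature mask.  ``*_p01`` masks use
    two-sided alpha = 0.01, ``*_p10`` the 0.10 display threshold.
    """

    percentile_map: np.ndarray
    positive_mask_p01: np.ndarray
    negative_mask_p01: np.ndarray
    positive_mask_p10: np.ndarray
    negative_mask_p10: np.ndarray
    p_pos: np.ndarray             # per-feature add-one p, positive direction
    p_neg: np.ndarray
    mask: FeatureMask


def permute_labels(
    labels,
    subject_ids,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    within_subject: bool = True,
) -> np.ndarray:
    """Random relabelings of the training examples, reproducible from seed.

    Returns an (n_permutations, n_examples) integer array.  Within-subject
    mode shuffles each subject's labels among that subject's examples,
    preserving per-subject class counts; otherwise the pooled label vector
    is shuffled.
    """
    y = np.asarray(labels)
    sids = np.asarray(subject_ids, dtype=object)
    if y.shape != sids.shape:
        raise PermutationError("labels and subject_ids must align")
    if n_permutations < 0:
        raise PermutationError("n_permutations must be >= 0")
    rng = np.random.default_rng(seed)
    out = np.empty((n_permutations, y.size), dtype=y.dtype)
    if within_subject:
        groups = [np.flatnonzero(sids == sid) for sid in dict.fromkeys(sids)]
        for p in range(n_permutations):
            perm = y.copy()
            for idx in groups:
                perm[idx] = y[idx][rng.permutation(idx.size)]
            out[p] = perm
    else:
        for p in range(n_permutations):
            out[p] = y[rng.permutation(y.size)]
    return out


def build_null(
    matrix: np.ndarray,
    permuted_labels: np.ndarray,
    c_param: float = DEFAULT_C,
    seed: int = 0,
    tol: float = PERMUTATION_TOL,
) -> PermutationNull:
    """Retrain the SVM under each relabeling; keep only the weight vectors.

    The linear Gram matrix is computed once and reused.  Individual
    failures are tolerated up to 5% of permutations, then the build aborts.
    """
    X = np.asarray(matrix, dtype=float)
    permuted_labels = np.atleast_2d(np.asarray(permuted_labels))
    n_perm = permuted_labels.shape[0] if permuted_labels.size else 0
    if n_perm == 0:
        return PermutationNull(null_weights=np.empty((0, X.shape[1])), seed=seed, c_param=c_param)
    K = precompute_kernel(X)
    weights = np.empty((n_perm, X.shape[1]))
    failures = 0
    max_failures = max(1, int(0.05 * n_perm))
    kept = 0
    for p in range(n_perm):
        try:
            model = train_from_kernel(K, X, permuted_labels[p], c_param, tol=tol)
        except SVMError as exc:
            failures += 1
            logger.warning("permutation %d failed to train: %s", p, exc)
            if failures > max_failures:
                raise PermutationError(
                    f"{failures} of {p + 1} permutations failed (> 5%); aborting"
                ) from exc
            continue
        weights[kept] = model.weights
        kept += 1
    return PermutationNull(null_weights=weights[:kept], seed=seed, c_param=c_param)


def _flat_percentiles(true_w: np.ndarray, null_w: np.ndarray) -> np.ndarray:
    """Mid-rank percentile of each true weight within its voxel's null."""
    less = (null_w < true_w).sum(axis=0)
    equal = (null_w == true_w).sum(axis=0)
    return 100.0 * (less + 0.5 * equal) / null_w.shape[0]


def significance_map(
    true_model: LinearModel,
    null: PermutationNull,
    mask: FeatureMask,
    alphas: tuple[float, float] = (0.01, 0.10),
) -> SignificanceMap:
    """Rank the true weight map against the permutation null, voxelwise.

    Positive (pain-predictive) and negative masks are built at each
    two-sided alpha from add-one permutation p-values; the percentile map
    is mid-rank, scaled 0-100, NaN outside the feature mask.
    """
    if null.n_permutations == 0:
        raise PermutationError("empty permutation null; run build_null with n_permutations > 0")
    if true_model.n_features != mask.n_features:
        raise PermutationError(
            f"model has {true_model.n_features} features, mask {mask.n_features}"
        )
    if null.null_weights.shape[1] != mask.n_features:
        raise PermutationError("null weight dimension does not match the feature mask")
    w = true_model.weights
    nw = null.null_weights
    n = null.n_permutations
    pct = _flat_percentiles(w, nw)
    # add-one permutation p-values, one per direction
    p_pos = (1.0 + (nw >= w).sum(axis=0)) / (n + 1.0)
    p_neg = (1.0 + (nw <= w).sum(axis=0)) / (n + 1.0)

    def masks_at(alpha: float) -> tuple[np.ndarray, np.ndarray]:
        pos = mask.unmask((p_pos <= alpha / 2).astype(float), fill=0.0).astype(bool)
        neg = mask.unmask((p_neg <= alpha / 2).astype(float), fill=0.0).astype(bool)
        return pos, neg

    pos01, neg01 = masks_at(alphas[0])
    pos10, neg10 = masks_at(alphas[1])
    return SignificanceMap(
        percentile_map=mask.unmask(pct),
        positive_mask_p01=pos01,
        negative_mask_p01=neg01,
        positive_mask_p10=pos10,
        negative_mask_p10=neg10,
        p_pos=p_pos,
        p_neg=p_neg,
        mask=mask,
    )


def flagged_fraction(sig: SignificanceMap, alpha: float) -> float:
    """Fraction of in-mask voxels flagged in either direction at ``alpha``."""
    flagged = (sig.p_pos <= alpha / 2) | (sig.p_neg <= alpha / 2)
    return float(flagged.mean())
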