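"""Model/Results interface for the whole-brain pain decoder.

:class:`PainDecoder` holds a training design (example matrix, labels,
subject ids, feature mask); ``fit()`` runs the linear SVM and returns a
:class:`PainDecoderResults` carrying the weight map, bias and everything
that hangs off a trained decoder: held-out evaluation, confidence-rejection
curves, permutation-based weight significance and a text summary.

    >>> dec = PainDecoder(X_train, y_train, subject_ids=ids, mask=mask)
    >>> res = dec.fit()
    >>> perf = res.evaluate(X_test, y_test, test_ids)
    >>> print(perf.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import confidence, evaluation, permutation, svm
from .extraction import ExampleMap, FeatureMask, vectorize_examples


class PainDecoder:
    """Linear SVM decoder of painful vs non-painful stimuli.

    Parameters
    ----------
    matrix : (n_examples, n_features) array
        Percent-signal-change features (raw percent units, no rescaling).
    labels : array of +1/-1
        +1 painful, -1 non-painful.
    subject_ids : array of str, optional
        Needed for per-subject evaluation and within-subject permutations.
    mask : FeatureMask, optional
        Fixes the voxel geometry of the feature columns; required to write
        weight or significance volumes.
    c_param : float
        Soft-margin regularization C (default 10), interpreted on the raw
        percent-change feature scale.
    """

    def __init__(self, matrix, labels, subject_ids=None, mask: FeatureMask | None = None,
                 c_param: float = svm.DEFAULT_C):
        self.matrix = np.asarray(matrix, dtype=float)
        self.labels = np.asarray(labels)
        self.subject_ids = None if subject_ids is None else np.asarray(subject_ids, dtype=object)
        self.mask = mask
        self.c_param = float(c_param)

    @classmethod
    def from_examples(cls, examples: list[ExampleMap], mask: FeatureMask,
                      c_param: float = svm.DEFAULT_C) -> "PainDecoder":
        """Build from per-stimulus example maps and a frozen feature mask."""
        X, y, sids = vectorize_examples(examples, mask)
        return cls(X, y, subject_ids=sids, mask=mask, c_param=c_param)

    @property
    def nobs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def fit(self, tol: float = svm.DEFAULT_TOL) -> "PainDecoderResults":
        model = svm.train(self.matrix, self.labels, c_param=self.c_param, tol=tol)
        return PainDecoderResults(decoder=self, model=model)


@dataclass
class PainDecoderResults:
    """Fitted decoder: weight map W, bias Z and derived analyses."""

    decoder: PainDecoder
    model: svm.LinearModel

    @property
    def weights(self) -> np.ndarray:
        return self.model.weights

    @property
    def bias(self) -> float:
        return self.model.bias

    def weight_map(self) -> np.ndarray:
        """Weights placed back into the 3D grid (NaN outside the mask)."""
        if self.decoder.mask is None:
            raise ValueError("decoder has no feature mask; cannot build a volume")
        return self.decoder.mask.unmask(self.weights)

    def decide(self, matrix) -> list[svm.DecisionResult]:
        return svm.decide_batch(self.model, np.atleast_2d(matrix))

    def predict(self, matrix) -> np.ndarray:
        return np.array([d.predicted_label for d in self.decide(matrix)])

    def training_objective(self) -> float:
        return svm.objective(self.model, self.decoder.matrix, self.decoder.labels)

    def evaluate(self, matrix, labels, subject_ids,
                 chance_level: float = evaluation.CHANCE_LEVEL) -> evaluation.PerformanceSummary:
        """Per-subject accuracy/PPV/NPV and group t-test on held-out data."""
        return evaluation.evaluate_by_subject(
            labels, self.predict(matrix), subject_ids, chance_level
        )

    def exclusion_curve(self, matrix, labels, fractions=None) -> confidence.ExclusionCurve:
        return confidence.exclusion_curve(self.decide(matrix), labels, fractions)

    def evaluate_with_rejection(
        self, matrix, labels, subject_ids,
        exclusion_fraction: float = confidence.DEFAULT_EXCLUSION_FRACTION,
    ) -> tuple[evaluation.PerformanceSummary, float]:
        """Evaluate after excluding the least-confident fraction of stimuli.

        Returns the summary over kept stimuli and the distance threshold
        that the fraction induced on this cohort.
        """
        decisions = self.decide(matrix)
        kept, _, threshold = confidence.apply_threshold(decisions, exclusion_fraction)
        labels = np.asarray(labels)
        subject_ids = np.asarray(subject_ids, dtype=object)
        predicted = np.array([decisions[i].predicted_label for i in kept])
        summary = evaluation.evaluate_by_subject(labels[kept], predicted, subject_ids[kept])
        return summary, threshold

    def permutation_significance(
        self,
        n_permutations: int = permutation.DEFAULT_N_PERMUTATIONS,
        seed: int = 0,
        within_subject: bool = True,
        alphas: tuple[float, float] = (0.01, 0.10),
    ) -> permutation.SignificanceMap:
        """Permutation-null significance of the voxel weights (see
        :mod:`painmvpa.permutation`)."""
        if within_subject and self.decoder.subject_ids is None:
            raise ValueError("within-subject permutation needs subject_ids")
        if self.decoder.mask is None:
            raise ValueError("significance maps need the decoder's feature mask")
        perms = permutation.permute_labels(
            self.decoder.labels,
            self.decoder.subject_ids if within_subject else np.zeros(self.decoder.nobs, dtype=object),
            n_permutations,
            seed=seed,
            within_subject=within_subject,
        )
        null = permutation.build_null(self.decoder.matrix, perms, self.decoder.c_param, seed=seed)
        return permutation.significance_map(self.model, null, self.decoder.mask, alphas)

    def summary(self) -> str:
        lines = [
            "Linear SVM pain decoder",
            "=" * 40,
            f"training examples:   {self.decoder.nobs}",
            f"features (voxels):   {self.decoder.n_features}",
            f"C (regularization):  {self.model.c_param:g}",
            f"|W| (weight norm):   {self.model.weight_norm:.6g}",
            f"Z (bias):            {self.model.bias:.6g}",
            f"training objective:  {self.training_objective():.6g}",
        ]
        train_acc = 100.0 * float(
            np.mean(self.predict(self.decoder.matrix) == self.decoder.labels)
        )
        lines.append(f"training accuracy:   {train_acc:.1f}%")
        return "\n".join(lines)
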