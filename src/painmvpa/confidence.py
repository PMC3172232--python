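"""Reject-option analysis: performance as a function of excluded stimuli.

Stimuli whose example maps lie nearest the separating hyperplane are the
hardest to classify; excluding them trades coverage for accuracy.  For an
exclusion fraction ``f`` the ``floor(f * n)`` examples with the smallest
geometric distance are dropped — pooled over all test subjects — and
accuracy/PPV/NPV are recomputed on the remainder.  The resulting curve is
summarized with a least-squares cubic, and a chosen operating fraction
(15% in the emulated study) yields a distance threshold that can either be
re-derived per cohort (default, keeping the excluded fraction fixed) or
frozen and re-applied as an absolute distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import METRICS, confusion_metrics
from .svm import DecisionResult

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSION_FRACTION = 0.15


class ConfidenceError(ValueError):
    pass


def _distances(decisions: list[DecisionResult]) -> np.ndarray:
    return np.array([d.distance for d in decisions], dtype=float)


def _predictions(decisions: list[DecisionResult]) -> np.ndarray:
    return np.array([d.predicted_label for d in decisions], dtype=int)


def apply_threshold(
    decisions: list[DecisionResult],
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Drop the ``floor(f * n)`` least-confident examples.

    Returns ``(kept_indices, excluded_indices, threshold_distance)`` where
    the threshold is the geometric distance of the last excluded example
    (0.0 when nothing is excluded), so it can be frozen and re-applied to a
    new cohort as an absolute cut.  Ties at the threshold are broken by
    stable input order.
    """
    if not 0 <= exclusion_fraction < 1:
        raise ConfidenceError("exclusion_fraction must lie in [0, 1)")
    n = len(decisions)
    if n == 0:
        raise ConfidenceError("no decisions to threshold")
    k = int(np.floor(exclusion_fraction * n))
    dist = _distances(decisions)
    order = np.argsort(dist, kind="stable")
    excluded = order[:k]
    kept = order[k:]
    if k > 0 and dist.max() == dist.min():
        logger.warning("all %d distances equal; excluding the first %d in input order", n, k)
    threshold = float(dist[excluded[-1]]) if k > 0 else 0.0
    return np.sort(kept), np.sort(excluded), threshold


def apply_absolute_threshold(
    decisions: list[DecisionResult], threshold_distance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Frozen-threshold variant: exclude every example with distance <= cut."""
    dist = _distances(decisions)
    excluded = np.flatnonzero(dist <= threshold_distance)
    kept = np.flatnonzero(dist > threshold_distance)
    return kept, excluded


@dataclass
class ExclusionCurve:
    """Metrics versus excluded fraction, with cubic-polynomial summaries.

    ``poly_coeffs[metric]`` holds 4 ascending-power coefficients
    (c0 + c1 f + c2 f^2 + c3 f^3) or None where the curve has fewer than 4
    defined points.  Values are NaN where a metric is undefined after
    exclusion (e.g. no predictions of one class remain).
    """

    fractions: np.ndarray
    accuracy: np.ndarray
    ppv: np.ndarray
    npv: np.ndarray
    poly_coeffs: dict[str, np.ndarray | None]

    def metric(self, name: str) -> np.ndarray:
        if name not in METRICS:
            raise ConfidenceError(f"unknown metric {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction_excluded": self.fractions,
                "accuracy": self.accuracy,
                "ppv": self.ppv,
                "npv": self.npv,
            }
        )


def fit_cubic(fractions, values) -> tuple[np.ndarray, float]:
    """Least-squares cubic fit; returns (ascending coefficients, residual SS).

    NaN values are dropped; at least 4 defined points are required.
    """
    f = np.asarray(fractions, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    f, v = f[ok], v[ok]
    if f.size < 4:
        raise ConfidenceError(f"cubic fit needs >= 4 defined points, got {f.size}")
    coeffs = np.polynomial.polynomial.polyfit(f, v, deg=3)
    resid = float(((np.polynomial.polynomial.polyval(f, coeffs) - v) ** 2).sum())
    return coeffs, resid


def exclusion_curve(
    decisions: list[DecisionResult],
    true_labels,
    fractions=None,
) -> ExclusionCurve:
    """Accuracy/PPV/NPV after excluding each fraction of least-confident stimuli.

    Distances are pooled over all examples (all test subjects together).
    The value at fraction 0 equals the unthresholded metric.
    """
    t = np.asarray(true_labels)
    if len(decisions) != t.size:
        raise ConfidenceError("decisions and true labels must align")
    if fractions is None:
        fractions = np.arange(0.0, 0.51, 0.05)
    fractions = np.asarray(fractions, dtype=float)
    if fractions.min() < 0 or fractions.max() >= 1:
        raise ConfidenceError("fractions must lie in [0, 1)")
    pred = _predictions(decisions)
    curves = {m: np.full(fractions.size, np.nan) for m in METRICS}
    for idx, f in enumerate(fractions):
        kept, _, _ = apply_threshold(decisions, float(f))
        if kept.size == 0:
            raise ConfidenceError(f"fraction {f} excludes every example")
        accuracy, ppv, npv = confusion_metrics(t[kept], pred[kept])
        curves["accuracy"][idx] = accuracy
        curves["ppv"][idx] = ppv
        curves["npv"][idx] = npv
    poly: dict[str, np.ndarray | None] = {}
    for m in METRICS:
        try:
            poly[m], _ = fit_cubic(fractions, curves[m])
        except ConfidenceError:
            poly[m] = None
    return ExclusionCurve(
        fractions=fractions,
        accuracy=curves["accuracy"],
        ppv=curves["ppv"],
        npv=curves["npv"],
        poly_coeffs=poly,
    )


def plot_exclusion_curve(curve: ExclusionCurve, ax=None):
    """Dots for measured metrics, solid lines for the cubic fits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(curve.fractions.min(), curve.fractions.max(), 200)
    for m in METRICS:
        pts = ax.plot(
            100 * curve.fractions, curve.metric(m), linestyle=":", marker="o",
            label=m.upper() if m != "accuracy" else "Accuracy",
        )
        if curve.poly_coeffs[m] is not None:
            ax.plot(
                100 * grid,
                np.polynomial.polynomial.polyval(grid, curve.poly_coeffs[m]),
                color=pts[0].get_color(),
            )
    ax.set_xlabel("Stimuli excluded (%)")
    ax.set_ylabel("Performance (%)")
    ax.legend()
    return ax
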