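"""Per-subject and group decoding performance: accuracy, PPV, NPV, t vs chance.

Accuracy is the percent of correctly classified stimuli.  PPV (positive
predictive value) is the percent of stimuli predicted painful that were
actually painful; NPV the percent predicted non-painful that were actually
non-painful.  When a subject has no positive (resp. negative) predictions
the corresponding metric is undefined and reported as missing, not zero;
missing values are dropped pairwise from group means and t-tests.

The group-level test is a two-sided one-sample t-test of the per-subject
percentages against the chance level (50% for the balanced 14/14 design),
with the sample standard deviation (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("accuracy", "ppv", "npv")
CHANCE_LEVEL = 50.0


class EvaluationError(ValueError):
    pass


def confusion_metrics(true_labels, predicted_labels) -> tuple[float, float, float]:
    """(accuracy, PPV, NPV) in percent for +1/-1 label vectors.

    PPV/NPV are NaN when no positive/negative predictions exist.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0:
        raise EvaluationError("empty label vectors")
    if t.shape != p.shape:
        raise EvaluationError(f"label vectors disagree in length: {t.shape} vs {p.shape}")
    bad = set(np.unique(np.concatenate([t, p]))) - {-1, 1}
    if bad:
        raise EvaluationError(f"labels must be +1/-1, found {sorted(bad)}")
    tp = int(np.sum((p == 1) & (t == 1)))
    tn = int(np.sum((p == -1) & (t == -1)))
    fp = int(np.sum((p == 1) & (t == -1)))
    fn = int(np.sum((p == -1) & (t == 1)))
    accuracy = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else np.nan
    npv = 100.0 * tn / (tn + fn) if (tn + fn) > 0 else np.nan
    return accuracy, ppv, npv


def group_t_test(
    per_subject_values, chance_level: float = CHANCE_LEVEL
) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of per-subject percentages vs chance.

    Returns ``(t, dof, p)``.  Missing (NaN) subjects are dropped.  With zero
    variance the statistic is reported as +/-inf (0 if the mean equals
    chance exactly).
    """
    values = np.asarray(per_subject_values, dtype=float)
    values = values[~np.isnan(values)]
    n = values.size
    if n < 2:
        raise EvaluationError("need at least 2 non-missing subjects for a t-test")
    dof = n - 1
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0.0:
        if mean == chance_level:
            return 0.0, dof, 1.0
        return float(np.sign(mean - chance_level)) * np.inf, dof, 0.0
    t = (mean - chance_level) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), dof, float(p)


@dataclass
class PerformanceSummary:
    """Per-subject and group decoding performance.

    ``per_subject`` has columns subject_id, accuracy, ppv, npv (percent).
    Group means/SDs use pairwise-complete values; ``tests`` maps each metric
    to its (t, dof, p) against ``chance_level``.
    """

    per_subject: pd.DataFrame
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    tests: dict[str, tuple[float, int, float]]
    chance_level: float = CHANCE_LEVEL

    @property
    def n_subjects(self) -> int:
        return len(self.per_subject)

    def significant(self, alpha: float = 0.05) -> dict[str, bool]:
        return {m: (t[2] < alpha) for m, t in self.tests.items()}

    def summary(self) -> str:
        """Human-readable table mirroring the per-subject report layout."""
        lines = [f"{'Subject':<12}{'Accuracy (%)':>14}{'PPV (%)':>10}{'NPV (%)':>10}"]
        for row in self.per_subject.itertuples():
            vals = [
                f"{getattr(row, m):.1f}" if np.isfinite(getattr(row, m)) else "--"
                for m in METRICS
            ]
            lines.append(f"{row.subject_id:<12}{vals[0]:>14}{vals[1]:>10}{vals[2]:>10}")
        avg = []
        for m in METRICS:
            mean, sd = self.group_mean[m], self.group_sd[m]
            star = "*" if self.tests.get(m, (0, 0, 1.0))[2] < 0.05 else ""
            cell = f"{mean:.1f}" if np.isfinite(mean) else "--"
            if np.isfinite(sd):
                cell += f"±{sd:.1f}"
            avg.append(cell + star)
        lines.append(f"{'Average':<12}{avg[0]:>14}{avg[1]:>10}{avg[2]:>10}")
        for m in METRICS:
            if m in self.tests:
                t, dof, p = self.tests[m]
                lines.append(f"{m}: t({dof}) = {t:.1f}, p = {p:.2g} vs chance {self.chance_level:g}%")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-subject table plus an Average row, for TSV export."""
        avg = {"subject_id": "Average"}
        for m in METRICS:
            avg[m] = self.group_mean[m]
        return pd.concat([self.per_subject, pd.DataFrame([avg])], ignore_index=True)


def summarize_group(
    per_subject: pd.DataFrame, chance_level: float = CHANCE_LEVEL
) -> PerformanceSummary:
    """Group-level summary of per-subject (accuracy, ppv, npv) percentages.

    ``per_subject`` needs columns subject_id, accuracy, ppv, npv.  With a
    single subject, SDs and t-tests are reported as missing.
    """
    if len(per_subject) < 1:
        raise EvaluationError("need at least one subject")
    group_mean: dict[str, float] = {}
    group_sd: dict[str, float] = {}
    tests: dict[str, tuple[float, int, float]] = {}
    for m in METRICS:
        values = per_subject[m].to_numpy(dtype=float)
        values = values[~np.isnan(values)]
        group_mean[m] = float(values.mean()) if values.size else np.nan
        group_sd[m] = float(values.std(ddof=1)) if values.size > 1 else np.nan
        if values.size >= 2:
            tests[m] = group_t_test(values, chance_level)
    return PerformanceSummary(
        per_subject=per_subject.reset_index(drop=True),
        group_mean=group_mean,
        group_sd=group_sd,
        tests=tests,
        chance_level=chance_level,
    )


def evaluate_by_subject(
    true_labels, predicted_labels, subject_ids, chance_level: float = CHANCE_LEVEL
) -> PerformanceSummary:
    """Compute per-subject confusion metrics and summarize the group.

    Subjects appear in order of first occurrence in ``subject_ids``.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    sids = np.asarray(subject_ids, dtype=object)
    if not (t.shape == p.shape == sids.shape):
        raise EvaluationError("labels and subject_ids must align")
    rows = []
    seen: list = []
    for sid in sids:
        if sid not in seen:
            seen.append(sid)
    for sid in seen:
        sel = sids == sid
        accuracy, ppv, npv = confusion_metrics(t[sel], p[sel])
        rows.append({"subject_id": sid, "accuracy": accuracy, "ppv": ppv, "npv": npv})
    return summarize_group(pd.DataFrame(rows), chance_level)
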