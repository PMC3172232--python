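"""Per-stimulus percent-signal-change maps and feature reduction.

Each heat stimulus becomes one *example*: a voxelwise map of percent BOLD
signal change,

    PSC = 100 * (mean stimulus signal - mean baseline signal) / mean baseline signal,

where the baseline signal is the 20 s preceding stimulus onset and the
stimulus signal is the block excluding its first 6 s (the hemodynamic rise),
i.e. the final 24 s of a 30 s block.  With TR = 2 s that is 10 baseline and
12 stimulus frames.  A frame belongs to a window when its acquisition onset
lies in the half-open interval [start, end).

Feature reduction intersects the gray-matter mask with an artifact filter:
any voxel whose |PSC| exceeds 3% in *any* training example is excluded,
since pain-evoked BOLD change is below 1% and larger changes are likely
artifactual.  The mask is built from training examples only and then frozen,
fixing the feature order for all later cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .simulate import RISE_SECONDS, BoldRun, SyntheticSubject

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...
BASELINE_WINDOW_SECONDS = 20.0
ARTIFACT_THRESHOLD_PCT = 3.0

PAIN_LABEL = 1
NONPAIN_LABEL = -1


class ExtractionError(ValueError):
    pass


@dataclass
class ExampleMap:
    """One stimulus's voxelwise percent-signal-change map plus metadata."""

    psc: np.ndarray               # 3D float, percent units
    subject_id: str
    run_id: str
    stimulus_index: int
    label: int                    # +1 painful, -1 nonpainful

    def __post_init__(self) -> None:
        if self.label not in (PAIN_LABEL, NONPAIN_LABEL):
            raise ExtractionError(f"label must be +1 or -1, got {self.label}")


@dataclass
class FeatureMask:
    """Boolean voxel-inclusion map fixing the feature order.

    ``feature_order`` is the flat (C-order) index of each included voxel;
    it defines the columns of every vectorized example matrix and the
    entries of every weight vector.
    """

    include: np.ndarray           # 3D bool
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        self.feature_order = np.flatnonzero(self.include)

    @property
    def n_features(self) -> int:
        return int(self.feature_order.size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.include.shape

    def unmask(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Place a feature vector back into the 3D grid."""
        values = np.asarray(values)
        if values.shape != (self.n_features,):
            raise ExtractionError(
                f"expected {self.n_features} values, got shape {values.shape}"
            )
        flat = np.full(int(np.prod(self.shape)), fill, dtype=float)
        flat[self.feature_order] = values
        return flat.reshape(self.shape)

    def save(self, path_prefix) -> None:
        """Write the mask as NIfTI plus a JSON sidecar recording provenance."""
        path_prefix = Path(path_prefix)
        affine = self.affine if self.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(self.include.astype(np.uint8), affine),
                 path_prefix.with_suffix(".nii"))
        sidecar = {
            "n_features": self.n_features,
            "shape": list(self.shape),
            "feature_order": "C-order flat indices of true voxels",
        }
        path_prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path_prefix) -> "FeatureMask":
        img = nib.load(Path(path_prefix).with_suffix(".nii"))
        return cls(include=np.asarray(img.dataobj).astype(bool), affine=img.affine)


def smooth_volume(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Spatially smooth every frame with a 3D Gaussian of given FWHM (mm).

    ``fwhm_mm = 0`` is the identity.  Voxel sizes come from the affine; for
    anisotropic voxels a per-axis sigma is used and a warning logged.
    """
    if fwhm_mm < 0:
        raise ExtractionError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return run
    voxel_sizes = np.sqrt((run.affine[:3, :3] ** 2).sum(axis=0))
    if not np.allclose(voxel_sizes, voxel_sizes[0], rtol=1e-6):
        logger.warning(
            "anisotropic voxels %s mm: using per-axis smoothing sigmas", voxel_sizes
        )
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / voxel_sizes
    smoothed = gaussian_filter(run.volume4d, sigma=(*sigma_vox, 0.0))
    return BoldRun(
        volume4d=smoothed,
        affine=run.affine,
        tr_seconds=run.tr_seconds,
        events=list(run.events),
        condition=run.condition,
        run_id=run.run_id,
    )


def window_frames(run: BoldRun, start_s: float, end_s: float) -> np.ndarray:
    """Indices of frames whose acquisition onset lies in [start_s, end_s)."""
    t = run.frame_times
    return np.flatnonzero((t >= start_s - 1e-9) & (t < end_s - 1e-9))


def extract_psc_map(
    run: BoldRun,
    event: tuple[float, float, str],
    subject_id: str = "",
    stimulus_index: int = 0,
    positive_condition: str = "painful",
    baseline_window_s: float = BASELINE_WINDOW_SECONDS,
    rise_s: float = RISE_SECONDS,
) -> ExampleMap:
    """Percent-signal-change map for a single stimulus event.

    The baseline window is ``[onset - baseline_window_s, onset)`` and the
    stimulus window ``[onset + rise_s, onset + duration)``.  Voxels with a
    zero baseline mean get NaN (and are reported via the logger).
    """
    onset, duration, trial_type = event
    run_end = run.n_frames * run.tr_seconds
    if onset - baseline_window_s < -1e-9 or onset + duration > run_end + 1e-9:
        raise ExtractionError(
            f"event (onset={onset}s, duration={duration}s, {trial_type!r}) windows "
            f"fall outside run [0, {run_end}s)"
        )
    base_idx = window_frames(run, onset - baseline_window_s, onset)
    stim_idx = window_frames(run, onset + rise_s, onset + duration)
    if base_idx.size == 0 or stim_idx.size == 0:
        raise ExtractionError(
            f"event (onset={onset}s, duration={duration}s) yields an empty window"
        )
    base_mean = run.volume4d[..., base_idx].mean(axis=-1)
    stim_mean = run.volume4d[..., stim_idx].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = 100.0 * (stim_mean - base_mean) / base_mean
    zero_base = base_mean == 0
    if zero_base.any():
        psc[zero_base] = np.nan
        logger.warning(
            "%d voxels with zero baseline mean set to NaN (event onset %ss)",
            int(zero_base.sum()), onset,
        )
    label = PAIN_LABEL if trial_type == positive_condition else NONPAIN_LABEL
    return ExampleMap(
        psc=psc,
        subject_id=subject_id,
        run_id=run.run_id,
        stimulus_index=stimulus_index,
        label=label,
    )


def extract_subject_examples(
    subject: SyntheticSubject,
    fwhm_mm: float = 0.0,
    positive_condition: str = "painful",
) -> list[ExampleMap]:
    """All per-stimulus example maps of one subject (optionally smoothed)."""
    examples: list[ExampleMap] = []
    index = 0
    for run in subject.runs:
        prepared = smooth_volume(run, fwhm_mm)
        for event in prepared.events:
            examples.append(
                extract_psc_map(
                    prepared,
                    event,
                    subject_id=subject.subject_id,
                    stimulus_index=index,
                    positive_condition=positive_condition,
                )
            )
            index += 1
    return examples


def build_feature_mask(
    gray_mask: np.ndarray,
    training_examples: list[ExampleMap],
    threshold_percent: float = ARTIFACT_THRESHOLD_PCT,
    affine: np.ndarray | None = None,
) -> FeatureMask:
    """Gray-matter mask minus artifact voxels, frozen from training data.

    A voxel survives iff it is gray matter and |PSC| <= threshold in every
    training example (NaN PSC also excludes).  The resulting mask fixes the
    feature space for all later test/retest cohorts.
    """
    gray_mask = np.asarray(gray_mask, dtype=bool)
    include = gray_mask.copy()
    for example in training_examples:
        if example.psc.shape != gray_mask.shape:
            raise ExtractionError(
                f"example grid {example.psc.shape} does not match mask {gray_mask.shape}"
            )
        with np.errstate(invalid="ignore"):
            ok = np.abs(example.psc) <= threshold_percent
        include &= ok
    if not include.any():
        raise ExtractionError("feature mask is empty after artifact exclusion")
    n_dropped = int(gray_mask.sum() - include.sum())
    if n_dropped:
        logger.info("artifact filter excluded %d of %d gray voxels", n_dropped, int(gray_mask.sum()))
    return FeatureMask(include=include, affine=affine)


def vectorize_examples(
    examples: list[ExampleMap], mask: FeatureMask
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack examples into an (n_examples, n_features) matrix.

    Row order preserves input order; columns follow ``mask.feature_order``.
    Values stay in raw percent units.  Returns ``(matrix, labels,
    subject_ids)``.
    """
    n = len(examples)
    if n == 0:
        raise ExtractionError("no examples to vectorize")
    X = np.empty((n, mask.n_features))
    labels = np.empty(n, dtype=int)
    subject_ids = np.empty(n, dtype=object)
    for i, example in enumerate(examples):
        if example.psc.shape != mask.shape:
            raise ExtractionError(
                f"example {i} grid {example.psc.shape} does not match mask {mask.shape}"
            )
        row = example.psc.reshape(-1)[mask.feature_order]
        bad = np.flatnonzero(~np.isfinite(row))
        if bad.size:
            raise ExtractionError(
                f"example {i} ({example.subject_id}/{example.run_id}) has non-finite "
                f"PSC inside the mask at feature indices {bad[:10].tolist()}"
            )
        X[i] = row
        labels[i] = example.label
        subject_ids[i] = example.subject_id
    return X, labels, subject_ids
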