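"""Sphere-ROI classifiers: can a single region decode pain on its own?

Each region of interest is an 8 mm sphere centered on a configured
MNI-like coordinate.  For every stimulus the mean percent signal change
over the sphere (intersected with the gray/feature mask) gives a single
scalar feature, and a per-ROI linear SVM is trained on the training group
and tested on held-out subjects — the single-region counterpart of the
whole-brain decoder.  A voxelwise-within-sphere mode keeps each sphere
voxel as a separate feature instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .atlas import sphere_voxels
from .evaluation import CHANCE_LEVEL, PerformanceSummary, evaluate_by_subject
from .extraction import ExampleMap
from .svm import DEFAULT_C, decide_batch, train

DEFAULT_RADIUS_MM = 8.0


class ROIError(ValueError):
    pass


@dataclass(frozen=True)
class ROISpec:
    """Named sphere in mm coordinates (e.g. S1, S2, insula, ACC, PFC, thalamus)."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = DEFAULT_RADIUS_MM

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ROIError(f"ROI {self.name!r}: radius must be positive")


def load_roi_config(path) -> list[ROISpec]:
    """Read ROI definitions from YAML/JSON: a list of {name, x, y, z, radius}."""
    entries = yaml.safe_load(Path(path).read_text())
    rois = []
    for e in entries:
        rois.append(
            ROISpec(
                name=str(e["name"]),
                center_mm=(float(e["x"]), float(e["y"]), float(e["z"])),
                radius_mm=float(e.get("radius", DEFAULT_RADIUS_MM)),
            )
        )
    return rois


def sphere_mask(roi: ROISpec, grid_shape, affine) -> np.ndarray:
    """Boolean voxel mask of the ROI sphere (voxel-center membership).

    Errors if the center maps outside the grid or the sphere contains no
    voxel centers.
    """
    inv = np.linalg.inv(affine)
    center_vox = inv[:3, :3] @ np.asarray(roi.center_mm, float) + inv[:3, 3]
    if np.any(center_vox < -0.5) or np.any(center_vox > np.asarray(grid_shape) - 0.5):
        raise ROIError(
            f"ROI {roi.name!r} center {roi.center_mm} maps to voxel {center_vox} "
            f"outside grid {tuple(grid_shape)}"
        )
    mask = sphere_voxels(roi.center_mm, roi.radius_mm, grid_shape, affine)
    if not mask.any():
        raise ROIError(f"ROI {roi.name!r}: sphere contains no voxel centers")
    return mask


def roi_features(
    examples: list[ExampleMap],
    rois: list[ROISpec],
    grid_shape,
    affine,
    gray_mask: np.ndarray | None = None,
) -> np.ndarray:
    """(n_examples, n_rois) matrix of mean PSC per ROI sphere.

    Spheres are intersected with ``gray_mask`` (e.g. the frozen feature
    mask) when given; an empty intersection is an error naming the ROI.
    """
    masks = []
    for roi in rois:
        m = sphere_mask(roi, grid_shape, affine)
        if gray_mask is not None:
            m = m & np.asarray(gray_mask, dtype=bool)
            if not m.any():
                raise ROIError(f"ROI {roi.name!r} does not intersect the gray/feature mask")
        masks.append(m)
    out = np.empty((len(examples), len(rois)))
    for i, example in enumerate(examples):
        if example.psc.shape != tuple(grid_shape):
            raise ROIError(f"example {i} grid {example.psc.shape} != {tuple(grid_shape)}")
        for j, m in enumerate(masks):
            out[i, j] = float(np.nanmean(example.psc[m]))
    return out


def roi_svm_evaluate(
    train_features: np.ndarray,
    train_labels,
    test_features: np.ndarray,
    test_labels,
    test_subject_ids,
    c_param: float = DEFAULT_C,
    chance_level: float = CHANCE_LEVEL,
) -> PerformanceSummary:
    """Train a (single-feature) SVM on one ROI and evaluate per test subject."""
    Xtr = np.atleast_2d(np.asarray(train_features, float))
    Xte = np.atleast_2d(np.asarray(test_features, float))
    if Xtr.ndim == 2 and Xtr.shape[0] == 1 and len(np.asarray(train_labels)) > 1:
        Xtr = Xtr.T
    if Xte.ndim == 2 and Xte.shape[0] == 1 and len(np.asarray(test_labels)) > 1:
        Xte = Xte.T
    model = train(Xtr, np.asarray(train_labels), c_param=c_param)
    decisions = decide_batch(model, Xte)
    predicted = [d.predicted_label for d in decisions]
    return evaluate_by_subject(test_labels, predicted, test_subject_ids, chance_level)
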