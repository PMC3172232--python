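"""End-to-end study orchestration: simulate, split, extract, train, test.

``run_study`` reproduces the full design of the emulated experiment on
synthetic data: a 16-subject cohort randomly split 8/8 into training and
testing groups, an independent 8-subject retest cohort, percent-signal-
change extraction behind a training-only feature mask, the whole-brain
decoder, confidence-rejection curves at the configured operating fraction,
permutation weight-significance maps and per-ROI classifiers.  Every stage
has its own seed so stages can be varied independently, and the report
carries provenance (config hash, seeds, version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import DEFAULT_GRID_SHAPE, DEFAULT_VOXEL_MM, Atlas, make_atlas
from .confidence import DEFAULT_EXCLUSION_FRACTION, ExclusionCurve
from .decoder import PainDecoder, PainDecoderResults
from .design import StudyDesign, make_design
from .evaluation import PerformanceSummary
from .extraction import build_feature_mask, extract_subject_examples, vectorize_examples
from .permutation import DEFAULT_N_PERMUTATIONS, SignificanceMap
from .roi import ROISpec, roi_features, roi_svm_evaluate
from .simulate import CohortParams, iter_cohort
from .svm import DEFAULT_C

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class StudyConfig:
    """Fully seeded configuration of one synthetic decoding study."""

    # geometry / design
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_mm: float = DEFAULT_VOXEL_MM
    design: dict = field(default_factory=dict)          # overrides for make_design
    # cohorts
    n_train_test: int = 16                               # split 8/8 by seed_split
    n_retest: int = 8
    gain_log_sigma: float = 0.2
    noise_sd: float = 0.5
    drift_amplitude: float = 0.1
    hemodynamic: str = "boxcar"
    # analysis
    fwhm_mm: float = 4.0
    artifact_threshold_pct: float = 3.0
    c_param: float = DEFAULT_C
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    # stage seeds
    seed_simulation: int = 0
    seed_retest: int = 1
    seed_split: int = 2
    seed_permutation: int = 3
    # atlas artifacts
    n_artifact_voxels: int = 5

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def split_groups(subject_ids, seed: int) -> tuple[list, list]:
    """Uniform random equal split of subjects into (training, testing)."""
    ids = list(subject_ids)
    if len(ids) < 2 or len(ids) % 2 != 0:
        raise PipelineError(f"need an even number (>= 2) of subjects, got {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    half = len(ids) // 2
    training = [ids[i] for i in sorted(order[:half])]
    testing = [ids[i] for i in sorted(order[half:])]
    return training, testing


@dataclass
class StudyReport:
    """Everything one study run produces."""

    config: StudyConfig
    design: StudyDesign
    atlas: Atlas
    training_ids: list
    testing_ids: list
    decoder_results: PainDecoderResults
    test_summary: PerformanceSummary
    retest_summary: PerformanceSummary
    test_thresholded: PerformanceSummary
    retest_thresholded: PerformanceSummary
    test_threshold_distance: float
    retest_threshold_distance: float
    test_curve: ExclusionCurve
    retest_curve: ExclusionCurve
    significance: SignificanceMap | None
    roi_table: pd.DataFrame
    n_examples: dict[str, int]
    provenance: dict


def _extract_group(design, atlas, n_subjects, cfg: StudyConfig, seed, prefix):
    params = CohortParams(
        gain_log_sigma=cfg.gain_log_sigma,
        noise_sd=cfg.noise_sd,
        drift_amplitude=cfg.drift_amplitude,
        hemodynamic=cfg.hemodynamic,
    )
    examples = []
    for subject in iter_cohort(n_subjects, design, atlas, params, seed, subject_prefix=prefix):
        examples.extend(extract_subject_examples(subject, fwhm_mm=cfg.fwhm_mm))
        logger.info("extracted %s (%d runs)", subject.subject_id, len(subject.runs))
    return examples


def run_study(config: StudyConfig, out_dir=None) -> StudyReport:
    """Run the complete synthetic decoding study described by ``config``.

    Deterministic given the config: identical configs give byte-identical
    numeric outputs.  If ``out_dir`` is given, tables (TSV), curve data,
    weight/percentile volumes (NIfTI) and a provenance log are written
    there.
    """
    design = make_design(**config.design)
    atlas = make_atlas(
        grid_shape=config.grid_shape,
        voxel_mm=config.voxel_mm,
        seed=config.seed_simulation,
        n_artifact_voxels=config.n_artifact_voxels,
    )

    main_examples = _extract_group(
        design, atlas, config.n_train_test, config, config.seed_simulation, "sub-"
    )
    retest_examples = _extract_group(
        design, atlas, config.n_retest, config, config.seed_retest, "ret-"
    )

    subject_ids = sorted({e.subject_id for e in main_examples})
    training_ids, testing_ids = split_groups(subject_ids, config.seed_split)
    train_examples = [e for e in main_examples if e.subject_id in set(training_ids)]
    test_examples = [e for e in main_examples if e.subject_id in set(testing_ids)]

    # leakage guard: the mask and model must never see testing-group data
    assert not {e.subject_id for e in train_examples} & set(testing_ids), \
        "testing subjects leaked into the training stage"

    mask = build_feature_mask(
        atlas.gray_mask, train_examples,
        threshold_percent=config.artifact_threshold_pct, affine=atlas.affine,
    )
    decoder = PainDecoder.from_examples(train_examples, mask, c_param=config.c_param)
    results = decoder.fit()

    Xte, yte, ste = vectorize_examples(test_examples, mask)
    Xre, yre, sre = vectorize_examples(retest_examples, mask)

    test_summary = results.evaluate(Xte, yte, ste)
    retest_summary = results.evaluate(Xre, yre, sre)
    test_thr, test_cut = results.evaluate_with_rejection(Xte, yte, ste, config.exclusion_fraction)
    retest_thr, retest_cut = results.evaluate_with_rejection(Xre, yre, sre, config.exclusion_fraction)
    test_curve = results.exclusion_curve(Xte, yte)
    retest_curve = results.exclusion_curve(Xre, yre)

    significance = None
    if config.n_permutations > 0:
        significance = results.permutation_significance(
            n_permutations=config.n_permutations, seed=config.seed_permutation
        )
    else:
        logger.warning("n_permutations=0: skipping weight-significance maps")

    # per-ROI classifiers at the planted (non-artifact) region centers
    rois = [
        ROISpec(name=r.name, center_mm=r.center_mm)
        for r in atlas.regions
        if not r.artifact
    ]
    roi_rows = []
    if rois:
        Ftr = roi_features(train_examples, rois, atlas.shape, atlas.affine, mask.include)
        Fte = roi_features(test_examples, rois, atlas.shape, atlas.affine, mask.include)
        ytr = np.array([e.label for e in train_examples])
        for j, roi in enumerate(rois):
            perf = roi_svm_evaluate(
                Ftr[:, j : j + 1], ytr, Fte[:, j : j + 1], yte, ste, c_param=config.c_param
            )
            row = {"roi": roi.name}
            for m in ("accuracy", "ppv", "npv"):
                row[m] = perf.group_mean[m]
                row[f"{m}_sd"] = perf.group_sd[m]
                row[f"{m}_p"] = perf.tests.get(m, (np.nan, 0, np.nan))[2]
            roi_rows.append(row)
    roi_table = pd.DataFrame(roi_rows)

    provenance = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "training_ids": training_ids,
        "testing_ids": testing_ids,
        "n_features": mask.n_features,
        "n_gray_voxels": atlas.n_gray,
    }

    report = StudyReport(
        config=config,
        design=design,
        atlas=atlas,
        training_ids=training_ids,
        testing_ids=testing_ids,
        decoder_results=results,
        test_summary=test_summary,
        retest_summary=retest_summary,
        test_thresholded=test_thr,
        retest_thresholded=retest_thr,
        test_threshold_distance=test_cut,
        retest_threshold_distance=retest_cut,
        test_curve=test_curve,
        retest_curve=retest_curve,
        significance=significance,
        roi_table=roi_table,
        n_examples={
            "training": len(train_examples),
            "testing": len(test_examples),
            "retest": len(retest_examples),
        },
        provenance=provenance,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: StudyReport, out_dir) -> None:
    """Write all study outputs (TSV/JSON/NIfTI) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.test_summary.to_frame().to_csv(out / "test_performance.tsv", sep="\t", index=False)
    report.retest_summary.to_frame().to_csv(out / "retest_performance.tsv", sep="\t", index=False)
    report.test_thresholded.to_frame().to_csv(
        out / "test_performance_thresholded.tsv", sep="\t", index=False
    )
    report.retest_thresholded.to_frame().to_csv(
        out / "retest_performance_thresholded.tsv", sep="\t", index=False
    )
    if len(report.roi_table):
        report.roi_table.to_csv(out / "roi_performance.tsv", sep="\t", index=False)
    for name, curve in (("test", report.test_curve), ("retest", report.retest_curve)):
        curve.to_frame().to_csv(out / f"exclusion_curve_{name}.tsv", sep="\t", index=False)
        coeffs = {
            m: (None if c is None else list(map(float, c)))
            for m, c in curve.poly_coeffs.items()
        }
        (out / f"exclusion_curve_{name}_cubic.json").write_text(json.dumps(coeffs, indent=2))
    affine = report.atlas.affine
    nib.save(
        nib.Nifti1Image(
            np.nan_to_num(report.decoder_results.weight_map()).astype(np.float32), affine
        ),
        out / "weight_map.nii",
    )
    if report.significance is not None:
        sig = report.significance
        nib.save(
            nib.Nifti1Image(np.nan_to_num(sig.percentile_map).astype(np.float32), affine),
            out / "weight_percentile_map.nii",
        )
        for attr in ("positive_mask_p01", "negative_mask_p01",
                     "positive_mask_p10", "negative_mask_p10"):
            nib.save(
                nib.Nifti1Image(getattr(sig, attr).astype(np.uint8), affine),
                out / f"{attr}.nii",
            )
    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=2))
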