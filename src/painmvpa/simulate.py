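"""Seeded synthetic "preprocessed" BOLD cohorts for the block-design study.

Each voxel time series is modelled multiplicatively around a constant
baseline intensity::

    s(v, t) = baseline * (1 + gain * e(v)/100 * r(t) + d(t) + n(v, t))

where ``e(v)`` is the planted percent-signal-change amplitude of the active
condition at voxel ``v``, ``r(t)`` is the stimulus response (a boxcar over
the steady-state stimulus window, delayed 6 s to emulate the hemodynamic
rise; a gamma-convolved option exists), ``d(t)`` is a per-run linear drift
and ``n`` is i.i.d. Gaussian noise per voxel-frame.  With zero noise and
drift, downstream percent-signal-change extraction recovers
``gain * e(v)`` exactly, which anchors the package's round-trip tests.

Datasets can be written to disk as NIfTI volumes plus BIDS-style TSV event
files and a JSON manifest, and read back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

from .atlas import Atlas
from .design import StudyDesign

RISE_SECONDS = 6.0  # hemodynamic rise allowance; matches the extraction window


class SimulationError(ValueError):
    pass


@dataclass
class BoldRun:
    """One functional run: 4D volume, geometry, timing and events."""

    volume4d: np.ndarray                      # (x, y, z, t)
    affine: np.ndarray                        # 4x4 voxel->mm
    tr_seconds: float
    events: list[tuple[float, float, str]]    # (onset_s, duration_s, trial_type)
    condition: str
    run_id: str = "run-01"

    def __post_init__(self) -> None:
        if self.volume4d.ndim != 4:
            raise SimulationError("volume4d must be 4D (x, y, z, time)")
        if self.tr_seconds <= 0:
            raise SimulationError("tr_seconds must be positive")
        run_end = self.volume4d.shape[3] * self.tr_seconds
        for onset, duration, _ in self.events:
            if onset + duration > run_end + 1e-9:
                raise SimulationError(
                    f"event at {onset}s (+{duration}s) extends past run end {run_end}s"
                )

    @property
    def n_frames(self) -> int:
        return self.volume4d.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition-onset time of each frame, seconds from run start."""
        return np.arange(self.n_frames) * self.tr_seconds


@dataclass
class SyntheticSubject:
    subject_id: str
    runs: list[BoldRun]
    gain: float
    noise_sd: float
    drift_amplitude: float

    def __post_init__(self) -> None:
        shapes = {run.volume4d.shape for run in self.runs}
        if len(shapes) > 1:
            raise SimulationError(f"runs of {self.subject_id} disagree on grid shape: {shapes}")


@dataclass(frozen=True)
class CohortParams:
    """Between-subject variability and noise settings for a cohort.

    ``gain_log_sigma`` is the SD of log per-subject amplitude gain
    (lognormal(0, sigma), so the median subject has gain 1).  ``noise_sd``
    is the per-voxel-frame Gaussian noise SD in percent-of-baseline units,
    fixed across subjects.  ``drift_amplitude`` is the peak-to-trough linear
    drift over one run, percent units.
    """

    gain_log_sigma: float = 0.2
    noise_sd: float = 0.5
    drift_amplitude: float = 0.1
    baseline: float = 1000.0
    hemodynamic: str = "boxcar"


def _gamma_hrf(tr: float, duration: float = 30.0) -> np.ndarray:
    """Single-gamma hemodynamic impulse response sampled at TR, peak-normalized."""
    t = np.arange(0.0, duration, tr)
    h = _gamma_dist.pdf(t, a=4.0, scale=1.5)  # peaks near 4.5 s
    return h / h.max()


def _response_timecourse(
    design: StudyDesign, events, frame_times: np.ndarray, hemodynamic: str
) -> np.ndarray:
    """Fraction-of-full-effect response at each frame time."""
    resp = np.zeros_like(frame_times)
    if hemodynamic == "boxcar":
        for onset, duration, _ in events:
            active = (frame_times >= onset + RISE_SECONDS) & (frame_times < onset + duration)
            resp[active] = 1.0
    elif hemodynamic == "gamma":
        stim = np.zeros_like(frame_times)
        for onset, duration, _ in events:
            stim[(frame_times >= onset) & (frame_times < onset + duration)] = 1.0
        h = _gamma_hrf(design.tr_seconds)
        conv = np.convolve(stim, h)[: len(stim)]
        plateau = h.sum()  # steady-state of convolving a long boxcar
        resp = conv / plateau
    else:
        raise SimulationError(f"unknown hemodynamic model {hemodynamic!r}")
    return resp


def simulate_run(
    design: StudyDesign,
    atlas: Atlas,
    condition: str,
    rng: np.random.Generator,
    gain: float = 1.0,
    noise_sd: float = 0.5,
    drift_amplitude: float = 0.1,
    baseline: float = 1000.0,
    hemodynamic: str = "boxcar",
    run_id: str = "run-01",
) -> BoldRun:
    """Simulate a single run of one condition."""
    if condition not in design.conditions:
        raise SimulationError(f"condition {condition!r} not in design conditions {design.conditions}")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    effect = atlas.effect_pain if condition == design.conditions[0] else atlas.effect_nonpain
    n_frames = design.volumes_per_run
    frame_times = np.arange(n_frames) * design.tr_seconds
    events = design.events(condition)
    resp = _response_timecourse(design, events, frame_times, hemodynamic)

    # fractional modulation: planted effect + drift + noise
    frac = (gain / 100.0) * effect[..., None] * resp[None, None, None, :]
    if drift_amplitude != 0.0:
        drift = (drift_amplitude / 100.0) * (frame_times / frame_times[-1] - 0.5)
        frac = frac + drift[None, None, None, :]
    if noise_sd > 0.0:
        frac = frac + rng.normal(0.0, noise_sd / 100.0, size=atlas.shape + (n_frames,))
    else:
        frac = np.broadcast_to(frac, atlas.shape + (n_frames,)).copy()
    volume = baseline * (1.0 + frac)
    if volume.min() <= 0:
        raise SimulationError("simulated intensities must stay strictly positive; lower noise_sd")
    return BoldRun(
        volume4d=volume,
        affine=atlas.affine,
        tr_seconds=design.tr_seconds,
        events=events,
        condition=condition,
        run_id=run_id,
    )


def run_conditions(design: StudyDesign) -> list[str]:
    """Condition of each run, alternating so drift cannot mimic the label."""
    return [design.conditions[r % len(design.conditions)] for r in range(design.runs_per_subject)]


def simulate_subject(
    design: StudyDesign,
    atlas: Atlas,
    subject_id: str = "sub-01",
    gain: float = 1.0,
    noise_sd: float = 0.5,
    drift_amplitude: float = 0.1,
    baseline: float = 1000.0,
    hemodynamic: str = "boxcar",
    seed: int | np.random.SeedSequence = 0,
) -> SyntheticSubject:
    """Simulate all runs of one subject (alternating conditions)."""
    rng = np.random.default_rng(seed)
    runs = [
        simulate_run(
            design,
            atlas,
            condition,
            rng,
            gain=gain,
            noise_sd=noise_sd,
            drift_amplitude=drift_amplitude,
            baseline=baseline,
            hemodynamic=hemodynamic,
            run_id=f"run-{r + 1:02d}",
        )
        for r, condition in enumerate(run_conditions(design))
    ]
    return SyntheticSubject(
        subject_id=subject_id,
        runs=runs,
        gain=gain,
        noise_sd=noise_sd,
        drift_amplitude=drift_amplitude,
    )


def iter_cohort(
    n_subjects: int,
    design: StudyDesign,
    atlas: Atlas,
    params: CohortParams | None = None,
    seed: int = 0,
    subject_prefix: str = "sub-",
):
    """Yield subjects one at a time (memory-friendly for large grids)."""
    if n_subjects < 1:
        raise SimulationError("n_subjects must be >= 1")
    params = params or CohortParams()
    children = np.random.SeedSequence(seed).spawn(n_subjects + 1)
    gains = np.random.default_rng(children[0]).lognormal(
        mean=0.0, sigma=params.gain_log_sigma, size=n_subjects
    )
    for i in range(n_subjects):
        yield simulate_subject(
            design,
            atlas,
            subject_id=f"{subject_prefix}{i + 1:02d}",
            gain=float(gains[i]),
            noise_sd=params.noise_sd,
            drift_amplitude=params.drift_amplitude,
            baseline=params.baseline,
            hemodynamic=params.hemodynamic,
            seed=children[i + 1],
        )


def simulate_cohort(
    n_subjects: int,
    design: StudyDesign,
    atlas: Atlas,
    params: CohortParams | None = None,
    seed: int = 0,
    subject_prefix: str = "sub-",
) -> list[SyntheticSubject]:
    """Simulate a cohort; reproducible from ``seed``.

    Per-subject gains are lognormal(0, ``gain_log_sigma``); noise SD is
    fixed across subjects.
    """
    return list(iter_cohort(n_subjects, design, atlas, params, seed, subject_prefix))


# ---------------------------------------------------------------------------
# dataset I/O


def write_dataset(cohort: list[SyntheticSubject], directory, atlas: Atlas) -> dict:
    """Write a cohort as NIfTI + TSV under ``directory``; returns the manifest.

    Layout: ``sub-XX/sub-XX_run-YY_bold.nii``, ``..._events.tsv``,
    ``gray_mask.nii`` and ``manifest.json`` at the dataset root.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"n_subjects": len(cohort), "subjects": []}
    nib.save(
        nib.Nifti1Image(atlas.gray_mask.astype(np.uint8), atlas.affine),
        directory / "gray_mask.nii",
    )
    manifest["gray_mask"] = "gray_mask.nii"
    for subject in cohort:
        sub_dir = directory / subject.subject_id
        sub_dir.mkdir(exist_ok=True)
        entry = {
            "subject_id": subject.subject_id,
            "gain": subject.gain,
            "noise_sd": subject.noise_sd,
            "drift_amplitude": subject.drift_amplitude,
            "runs": [],
        }
        for run in subject.runs:
            stem = f"{subject.subject_id}_{run.run_id}"
            bold_path = sub_dir / f"{stem}_bold.nii"
            events_path = sub_dir / f"{stem}_events.tsv"
            try:
                nib.save(
                    nib.Nifti1Image(run.volume4d.astype(np.float32), run.affine), bold_path
                )
                pd.DataFrame(
                    run.events, columns=["onset", "duration", "trial_type"]
                ).to_csv(events_path, sep="\t", index=False)
            except OSError as exc:  # pragma: no cover - disk failure path
                raise OSError(f"failed writing {bold_path}: {exc}") from exc
            entry["runs"].append(
                {
                    "run_id": run.run_id,
                    "condition": run.condition,
                    "tr_seconds": run.tr_seconds,
                    "bold": str(bold_path.relative_to(directory)),
                    "events": str(events_path.relative_to(directory)),
                }
            )
        manifest["subjects"].append(entry)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_dataset(directory) -> tuple[list[SyntheticSubject], np.ndarray, np.ndarray]:
    """Read back a dataset written by :func:`write_dataset`.

    Returns ``(subjects, gray_mask, affine)``.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    mask_img = nib.load(directory / manifest["gray_mask"])
    gray_mask = np.asarray(mask_img.dataobj).astype(bool)
    subjects = []
    for entry in manifest["subjects"]:
        runs = []
        for run_entry in entry["runs"]:
            img = nib.load(directory / run_entry["bold"])
            events_df = pd.read_csv(directory / run_entry["events"], sep="\t")
            events = [
                (float(r.onset), float(r.duration), str(r.trial_type))
                for r in events_df.itertuples()
            ]
            runs.append(
                BoldRun(
                    volume4d=np.asarray(img.dataobj, dtype=np.float64),
                    affine=img.affine,
                    tr_seconds=float(run_entry["tr_seconds"]),
                    events=events,
                    condition=run_entry["condition"],
                    run_id=run_entry["run_id"],
                )
            )
        subjects.append(
            SyntheticSubject(
                subject_id=entry["subject_id"],
                runs=runs,
                gain=entry["gain"],
                noise_sd=entry["noise_sd"],
                drift_amplitude=entry["drift_amplitude"],
            )
        )
    return subjects, gray_mask, mask_img.affine
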