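"""Block-design study timing for thermal-stimulation BOLD experiments.

The emulated protocol alternates an extended baseline period with a heat
stimulation period inside each functional run: 40 s at a non-noxious
baseline temperature followed by 30 s of heat, repeated 7 times per run,
sampled at TR = 2 s.  Each subject completes ``runs_per_condition`` runs
per condition (painful / non-painful heat), so with the defaults a subject
contributes 14 painful and 14 non-painful stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class DesignError(ValueError):
    """Raised when study timing parameters are inconsistent."""


@dataclass(frozen=True)
class StudyDesign:
    """Timing and structure of one block-design heat-stimulation study.

    Parameters
    ----------
    tr_seconds : float
        Repetition time (sampling interval) of the BOLD time series, seconds.
    baseline_seconds : float
        Duration of the baseline-temperature period preceding each heat block.
    stimulus_seconds : float
        Duration of each heat-stimulation block.
    blocks_per_run : int
        Number of baseline+heat cycles in one functional run.
    runs_per_condition : int
        Runs acquired per condition; each run presents a single condition.
    conditions : tuple of str
        Ordered condition labels ``(painful, nonpainful)``.
    """

    tr_seconds: float = 2.0
    baseline_seconds: float = 40.0
    stimulus_seconds: float = 30.0
    blocks_per_run: int = 7
    runs_per_condition: int = 2
    conditions: tuple[str, str] = ("painful", "nonpainful")

    def __post_init__(self) -> None:
        for name in ("tr_seconds", "baseline_seconds", "stimulus_seconds"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be positive, got {getattr(self, name)}")
        if self.blocks_per_run < 1 or self.runs_per_condition < 1:
            raise DesignError("blocks_per_run and runs_per_condition must be >= 1")
        if len(self.conditions) != 2:
            raise DesignError("exactly two conditions (painful, nonpainful) are required")
        n_vol = self.blocks_per_run * (self.baseline_seconds + self.stimulus_seconds) / self.tr_seconds
        if abs(n_vol - round(n_vol)) > 1e-9:
            raise DesignError(
                f"volumes per run must be an integer: {self.blocks_per_run} blocks x "
                f"({self.baseline_seconds}+{self.stimulus_seconds}) s / TR {self.tr_seconds} s "
                f"= {n_vol}"
            )

    @property
    def block_seconds(self) -> float:
        return self.baseline_seconds + self.stimulus_seconds

    @property
    def run_seconds(self) -> float:
        return self.blocks_per_run * self.block_seconds

    @property
    def volumes_per_run(self) -> int:
        return round(self.run_seconds / self.tr_seconds)

    @property
    def runs_per_subject(self) -> int:
        return self.runs_per_condition * len(self.conditions)

    @property
    def stimuli_per_condition(self) -> int:
        """Heat stimuli each subject receives per condition."""
        return self.blocks_per_run * self.runs_per_condition

    @property
    def examples_per_subject(self) -> int:
        """Total stimuli (= training/testing examples) per subject."""
        return self.stimuli_per_condition * len(self.conditions)

    def onsets(self) -> list[float]:
        """Stimulus-onset times (seconds from run start) for one run."""
        return [self.baseline_seconds + k * self.block_seconds for k in range(self.blocks_per_run)]

    def events(self, condition: str) -> list[tuple[float, float, str]]:
        """(onset, duration, trial_type) rows for a run of ``condition``."""
        return [(t, self.stimulus_seconds, condition) for t in self.onsets()]


def make_design(**overrides) -> StudyDesign:
    """Build a :class:`StudyDesign`, overriding any subset of the defaults.

    Raises
    ------
    DesignError
        If the overrides make the volumes-per-run count non-integer or any
        timing parameter non-positive.
    """
    base = StudyDesign()
    unknown = set(overrides) - set(base.__dataclass_fields__)
    if unknown:
        raise DesignError(f"unknown design parameters: {sorted(unknown)}")
    return replace(base, **overrides)
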