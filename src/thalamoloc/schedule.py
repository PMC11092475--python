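"""Clustered-sparse thalamic-localizer run schedules and timing arithmetic.

Each 12-second trial is: silent gap, 9 s of auditory or visual stimulation,
a second gap of equal duration, then a cluster of 3 BOLD volumes acquired
back-to-back.  The gaps are calibrated so the trial total is exact for the
site's TR (225 ms at TR 850 ms, 300 ms at TR 800 ms).  A run opens with one
fixation trial followed by 16 stimulus trials (8 auditory, 8 visual) in a
seeded pseudorandom order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimingParams",
    "TrialTiming",
    "TrialSchedule",
    "AuditoryTrialPlan",
    "compute_trial_timing",
    "build_run_schedule",
    "plan_auditory_trial",
    "write_events_table",
    "read_events_table",
    "TimingInfeasibleError",
    "InsufficientPoolError",
]

FIXATION = "fixation"
AUDITORY = "auditory"
VISUAL = "visual"

N_AUDITORY_TRIALS = 8
N_VISUAL_TRIALS = 8


class TimingInfeasibleError(ValueError):
    """Trial timing cannot fit within the total trial duration."""


class InsufficientPoolError(ValueError):
    """Not enough music segments to fill an auditory trial."""


@dataclass(frozen=True)
class TimingParams:
    """Acquisition-timing parameters of one site's localizer protocol."""

    tr_seconds: float
    volumes_per_cluster: int = 3
    stimulation_seconds: float = 9.0
    trial_total_seconds: float = 12.0

    def __post_init__(self) -> None:
        for name in ("tr_seconds", "stimulation_seconds", "trial_total_seconds"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.volumes_per_cluster < 1:
            raise ValueError("volumes_per_cluster must be >= 1")


@dataclass(frozen=True)
class TrialTiming:
    """Derived per-trial timing: gap duration and acquisition-cluster length."""

    gap_seconds: float
    cluster_seconds: float


@dataclass
class TrialSchedule:
    """An ordered list of trials with per-trial acquisition-volume onsets."""

    trials: list[tuple[str, float]]
    acquisition_times: list[list[float]]
    params: TimingParams
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_volumes(self) -> int:
        return sum(len(t) for t in self.acquisition_times)

    @property
    def conditions(self) -> list[str]:
        return [c for c, _ in self.trials]

    def condition_per_volume(self) -> np.ndarray:
        """Condition label for each acquired volume, in acquisition order."""
        return np.repeat(self.conditions, [len(a) for a in self.acquisition_times])

    def volume_in_cluster(self) -> np.ndarray:
        """1-based within-cluster position of each acquired volume."""
        return np.concatenate(
            [np.arange(1, len(a) + 1) for a in self.acquisition_times]
        )


@dataclass(frozen=True)
class AuditoryTrialPlan:
    """Nine 900 ms music segments, each followed by 100 ms of silence."""

    segment_ids: tuple
    segment_seconds: float = 0.9
    silence_seconds: float = 0.1

    @property
    def duration_seconds(self) -> float:
        return len(self.segment_ids) * (self.segment_seconds + self.silence_seconds)


def compute_trial_timing(params: TimingParams) -> TrialTiming:
    """Gap and cluster durations implied by the timing parameters.

    The acquisition cluster lasts ``volumes_per_cluster * TR``; the two equal
    gaps absorb whatever remains of the trial after stimulation.
    """
    cluster = params.volumes_per_cluster * params.tr_seconds
    gap = (params.trial_total_seconds - params.stimulation_seconds - cluster) / 2.0
    if gap < 0:
        raise TimingInfeasibleError(
            f"stimulation ({params.stimulation_seconds}s) + cluster ({cluster}s) "
            f"exceed trial total ({params.trial_total_seconds}s)"
        )
    return TrialTiming(gap_seconds=gap, cluster_seconds=cluster)


def build_run_schedule(
    params: TimingParams,
    seed: int,
    lead_in_seconds: float = 0.0,
    max_condition_run: int | None = None,
) -> TrialSchedule:
    """Build one run: a fixation trial then 16 stimulus trials, seeded.

    The condition order is a uniform seeded permutation of 8 auditory and
    8 visual trials.  ``max_condition_run`` optionally rejects permutations
    containing longer same-condition streaks.  Every trial, including the
    opening fixation, ends with an acquisition cluster.  ``lead_in_seconds``
    shifts all onsets to model dead time at the start of the run.
    """
    timing = compute_trial_timing(params)
    rng = np.random.default_rng(seed)
    stim = [AUDITORY] * N_AUDITORY_TRIALS + [VISUAL] * N_VISUAL_TRIALS
    while True:
        order = [stim[i] for i in rng.permutation(len(stim))]
        if max_condition_run is None or _max_streak(order) <= max_condition_run:
            break
    conditions = [FIXATION] + order

    trials: list[tuple[str, float]] = []
    acq: list[list[float]] = []
    acq_offset = 2 * timing.gap_seconds + params.stimulation_seconds
    for i, cond in enumerate(conditions):
        onset = lead_in_seconds + i * params.trial_total_seconds
        trials.append((cond, onset))
        acq.append(
            [onset + acq_offset + k * params.tr_seconds
             for k in range(params.volumes_per_cluster)]
        )
    return TrialSchedule(trials=trials, acquisition_times=acq, params=params, seed=seed)


def _max_streak(conditions: list[str]) -> int:
    best = run = 1
    for a, b in zip(conditions, conditions[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def plan_auditory_trial(pool, seed: int) -> AuditoryTrialPlan:
    """Sample 9 music segments without replacement in seeded order."""
    pool = list(pool)
    if len(pool) < 9:
        raise InsufficientPoolError(
            f"need at least 9 music segments, got {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=9, replace=False)
    return AuditoryTrialPlan(segment_ids=tuple(pool[i] for i in picks))


def write_events_table(schedule: TrialSchedule, path) -> Path:
    """Write a BIDS-style events TSV plus a JSON sidecar.

    The TSV has columns onset, duration, condition; the sidecar carries the
    acquisition-volume onsets, timing parameters, and seed so the schedule
    round-trips losslessly.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "onset": [t for _, t in schedule.trials],
            "duration": schedule.params.trial_total_seconds,
            "condition": schedule.conditions,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "acquisition_times": schedule.acquisition_times,
                "params": {
                    "tr_seconds": schedule.params.tr_seconds,
                    "volumes_per_cluster": schedule.params.volumes_per_cluster,
                    "stimulation_seconds": schedule.params.stimulation_seconds,
                    "trial_total_seconds": schedule.params.trial_total_seconds,
                },
                "seed": schedule.seed,
            },
            indent=1,
        )
    )
    return path


def read_events_table(path) -> TrialSchedule:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    params = TimingParams(**meta["params"])
    trials = list(zip(df["condition"].tolist(), df["onset"].tolist()))
    return TrialSchedule(
        trials=trials,
        acquisition_times=[list(a) for a in meta["acquisition_times"]],
        params=params,
        seed=int(meta["seed"]),
    )
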