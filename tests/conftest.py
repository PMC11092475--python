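"""Shared fixtures: phantom anatomy and one full localizer run.

The localizer run on the default phantom is expensive (~10 s), so it is
computed once per session and shared by the fROI, QC, and recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from thalamoloc.phantom import (
    TaskEffectSpec,
    make_phantom_anatomy,
    simulate_motion_and_eyes,
    simulate_task_run,
)
from thalamoloc.pipeline import TaskRun, run_localizer
from thalamoloc.schedule import TimingParams, build_run_schedule

PHANTOM_TR = 0.85


@pytest.fixture(scope="session")
def anatomy():
    return make_phantom_anatomy()


@pytest.fixture(scope="session")
def task_runs(anatomy):
    """Four clustered-sparse task runs at the default (moderate) SNR."""
    params = TimingParams(tr_seconds=PHANTOM_TR)
    runs = []
    for r in range(4):
        sched = build_run_schedule(params, seed=100 + r)
        series, _ = simulate_task_run(anatomy, sched, TaskEffectSpec(), seed=100 + r)
        motion, _ = simulate_motion_and_eyes(series.n_volumes, PHANTOM_TR, seed=100 + r)
        runs.append(TaskRun(series=series, schedule=sched, motion=motion))
    return runs


@pytest.fixture(scope="session")
def localizer_output(anatomy, task_runs):
    return run_localizer(anatomy.labels, anatomy.labels, task_runs)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
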