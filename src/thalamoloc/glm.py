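"""Sparse-acquisition design matrix, voxelwise OLS, and the A-V contrast.

The task design matrix carries, for each run, 19 columns: intercept,
auditory and visual indicators (unconvolved 0/1 over acquired volumes — the
clustered-sparse sampling precludes a continuous HRF model), 6 motion
parameters and their squares, mean WM and CSF signals, and indicators for
the second and third volume of each acquisition cluster (absorbing the
T1-relaxation decay of non-steady-state volumes).  Runs are assembled
block-diagonally, so each run's columns occupy only its rows; fixation
volumes are the implicit baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import MaskVolume, VolumeImage, VolumeSeries, require_same_grid
from .schedule import AUDITORY, VISUAL, TrialSchedule

__all__ = [
    "DesignMatrix",
    "BetaMaps",
    "build_design_matrix",
    "fit_glm",
    "contrast_auditory_minus_visual",
    "RankDeficientError",
]

RUN_COLUMNS = (
    ["intercept", "auditory", "visual"]
    + [f"motion_{i}" for i in range(1, 7)]
    + [f"motion_sq_{i}" for i in range(1, 7)]
    + ["wm", "csf", "cluster_vol2", "cluster_vol3"]
)


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (total volumes, n_regressors)
    column_names: list[str]
    run_blocks: list[tuple[int, int]]  # per-run [start, stop) row ranges

    @property
    def n_runs(self) -> int:
        return len(self.run_blocks)

    def columns_like(self, base: str) -> list[str]:
        """All per-run columns for a base name, e.g. 'auditory'."""
        return [c for c in self.column_names if c.endswith(f"_{base}")]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names)


@dataclass
class BetaMaps:
    """Per-regressor beta volumes from a voxelwise OLS fit."""

    betas: dict[str, np.ndarray]  # column name -> 3D map
    residual_variance: np.ndarray
    affine: np.ndarray
    mask: MaskVolume
    design: DesignMatrix


def _cluster_indicator(schedule: TrialSchedule, position: int) -> np.ndarray:
    return (schedule.volume_in_cluster() == position).astype(float)


def _condition_indicator(schedule: TrialSchedule, condition: str) -> np.ndarray:
    return (schedule.condition_per_volume() == condition).astype(float)


def build_design_matrix(
    schedules: list[TrialSchedule],
    motion: list[np.ndarray | pd.DataFrame],
    wm: list[np.ndarray],
    csf: list[np.ndarray],
    center_nuisance: bool = True,
) -> DesignMatrix:
    """Assemble the block-diagonal multi-run task design matrix.

    ``motion`` holds one (volumes x 6) table per run; ``wm``/``csf`` one mean
    compartment series per run.  WM/CSF columns are mean-centered per run by
    default so condition betas keep their baseline-relative interpretation.
    Motion parameters enter raw plus squared.
    """
    n_runs = len(schedules)
    if not (len(motion) == len(wm) == len(csf) == n_runs):
        raise ValueError("schedules, motion, wm, csf must have one entry per run")
    per_run = []
    for r, sched in enumerate(schedules):
        n_vol = sched.n_volumes
        mp = np.asarray(motion[r], dtype=float)
        if mp.shape != (n_vol, 6):
            raise ValueError(
                f"run {r}: motion table shape {mp.shape} != ({n_vol}, 6)"
            )
        wm_r = np.asarray(wm[r], dtype=float).reshape(-1)
        csf_r = np.asarray(csf[r], dtype=float).reshape(-1)
        if len(wm_r) != n_vol or len(csf_r) != n_vol:
            raise ValueError(f"run {r}: WM/CSF series length != {n_vol}")
        if center_nuisance:
            wm_r = wm_r - wm_r.mean()
            csf_r = csf_r - csf_r.mean()
        block = np.column_stack(
            [
                np.ones(n_vol),
                _condition_indicator(sched, AUDITORY),
                _condition_indicator(sched, VISUAL),
                mp,
                mp**2,
                wm_r,
                csf_r,
                _cluster_indicator(sched, 2),
                _cluster_indicator(sched, 3),
            ]
        )
        per_run.append(block)

    total = sum(b.shape[0] for b in per_run)
    width = len(RUN_COLUMNS)
    matrix = np.zeros((total, width * n_runs))
    names: list[str] = []
    blocks: list[tuple[int, int]] = []
    row = 0
    for r, block in enumerate(per_run):
        n_vol = block.shape[0]
        matrix[row : row + n_vol, r * width : (r + 1) * width] = block
        names += [f"run{r}_{c}" for c in RUN_COLUMNS]
        blocks.append((row, row + n_vol))
        row += n_vol
    return DesignMatrix(matrix=matrix, column_names=names, run_blocks=blocks)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[i] for i in np.flatnonzero(diag <= tol)]


def fit_glm(series: VolumeSeries, design: DesignMatrix, mask: MaskVolume) -> BetaMaps:
    """Voxelwise ordinary least squares within a mask.

    Raises :class:`RankDeficientError` naming the collinear columns if the
    design is not full column rank.
    """
    require_same_grid(series, mask)
    X = design.matrix
    if X.shape[0] != series.n_volumes:
        raise ValueError(
            f"design has {X.shape[0]} rows but series has {series.n_volumes} volumes"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, design.column_names)
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}"
        )
    Y = series.data[mask.data].T.astype(float)  # (T, V)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    res_var = (resid**2).sum(axis=0) / dof

    shape = series.data.shape[:3]
    betas = {}
    for i, name in enumerate(design.column_names):
        vol = np.zeros(shape)
        vol[mask.data] = beta[i]
        betas[name] = vol
    rv = np.zeros(shape)
    rv[mask.data] = res_var
    return BetaMaps(
        betas=betas,
        residual_variance=rv,
        affine=series.affine,
        mask=mask,
        design=design,
    )


def contrast_auditory_minus_visual(betas: BetaMaps) -> VolumeImage:
    """Auditory minus visual beta per voxel, averaged across runs."""
    aud = betas.design.columns_like("auditory")
    vis = betas.design.columns_like("visual")
    if not aud or not vis:
        raise KeyError("design has no auditory/visual columns")
    if len(aud) != len(vis):
        raise KeyError("mismatched auditory/visual columns across runs")
    diff = np.mean(
        [betas.betas[a] - betas.betas[v] for a, v in zip(aud, vis)], axis=0
    )
    return VolumeImage(diff, betas.affine)
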