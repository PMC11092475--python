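"""Shared numerics: residualization and partial correlation."""

from __future__ import annotations

import numpy as np

__all__ = ["residualize", "partial_correlation", "partial_correlation_map"]

#: residual standard deviation below which a series is treated as constant
DEGENERATE_TOL = 1e-12


def _with_intercept(nuisance: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if nuisance is None or nuisance.size == 0:
        return ones
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    if nuisance.shape[0] != n:
        raise ValueError(
            f"nuisance has {nuisance.shape[0]} rows, expected {n}"
        )
    return np.column_stack([ones, nuisance])


def residualize(y: np.ndarray, nuisance: np.ndarray | None) -> np.ndarray:
    """OLS residuals of ``y`` (T,) or (T, k) on nuisance columns + intercept."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X = _with_intercept(nuisance, n)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, nuisance: np.ndarray | None = None
) -> float:
    """Pearson correlation of ``x`` and ``y`` after removing nuisance signal.

    Both series are residualized on the nuisance matrix (plus an intercept)
    and the residuals correlated.  If either residual is (numerically)
    constant the correlation is undefined and 0.0 is returned.
    """
    rx = residualize(np.asarray(x, float), nuisance)
    ry = residualize(np.asarray(y, float), nuisance)
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    if sx < DEGENERATE_TOL * max(1.0, np.abs(x).max()) or sx == 0:
        return 0.0
    if sy < DEGENERATE_TOL * max(1.0, np.abs(y).max()) or sy == 0:
        return 0.0
    return float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))


def partial_correlation_map(
    voxels: np.ndarray, reference: np.ndarray, nuisance: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Partial correlation of many voxel series (T, V) with one reference (T,).

    Returns ``(r, degenerate)`` where ``degenerate`` flags voxels whose
    residual was constant (their r is set to 0).
    """
    voxels = np.asarray(voxels, dtype=float)
    reference = np.asarray(reference, dtype=float)
    rv = residualize(voxels, nuisance)
    rr = residualize(reference, nuisance)
    sr = np.sqrt(rr @ rr)
    sv = np.sqrt((rv * rv).sum(axis=0))
    scale = DEGENERATE_TOL * max(1.0, float(np.abs(voxels).max(initial=0.0)))
    degenerate = sv <= scale
    if sr <= DEGENERATE_TOL * max(1.0, float(np.abs(reference).max(initial=0.0))):
        return np.zeros(voxels.shape[1]), np.ones(voxels.shape[1], dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rv.T @ rr) / (sv * sr)
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0), degenerate
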