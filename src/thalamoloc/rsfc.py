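"""Resting-state post-processing, censoring, connectivity, and selectivity.

Processing order for each resting run: mode-1000 normalization, linear
detrend + mean centering, volume censoring (motion metrics or a precomputed
mask, plus eye-closure rules), retention pruning (segments under 8 s,
runs under 90 s, participants under 2 runs or 300 s), then band-pass
filtering (0.009-0.08 Hz second-order zero-phase Butterworth) with censored
points linearly interpolated beforehand, edge volumes (ceil(22 s / TR) per
end) discarded afterwards, and finally censored volumes dropped from
analysis.

ROI-pair connectivity averages four hemispheric Pearson partial correlations
(left/right seed x left/right target), controlling for 28 nuisance columns:
band-pass filtered motion parameters, their squares, their derivatives, the
squares of the derivatives, and WM/CSF signals with their derivatives.
Selectivity of the localized nuclei is tested with one-tailed paired t-tests
(MGN-AC > MGN-VC, MGN-AC > LGN-AC, LGN-VC > LGN-AC, LGN-VC > MGN-VC) under
Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from ._stats import partial_correlation, partial_correlation_map, residualize
from .imaging import MaskVolume, VolumeImage, VolumeSeries, require_same_grid

__all__ = [
    "CensorConfig",
    "ConnectivityEstimate",
    "mode1000_normalize",
    "detrend_center",
    "motion_metric_censor",
    "eye_closure_censor",
    "apply_retention_rules",
    "bandpass_filter",
    "edge_discard_count",
    "bandpass_with_interpolation",
    "build_rsfc_nuisance",
    "roi_pair_connectivity",
    "selectivity_tests",
    "seed_connectivity_map",
    "dice",
    "SELECTIVITY_CONTRASTS",
]


@dataclass(frozen=True)
class CensorConfig:
    """Censoring thresholds and retention rules.

    ``lpf_fd_threshold`` (mm) and ``gev_dv_parameter`` are consumed as given
    — they are optimized externally for a given acquisition protocol
    (0.07587 mm and 3.105 here); this module only applies them to
    precomputed per-volume motion metrics.  The remaining fields implement
    the eye-closure and retention rules.
    """

    lpf_fd_threshold: float = 0.07587
    gev_dv_parameter: float = 3.105
    eye_closure_min: float = 3.0
    eye_gap_merge: float = 30.0
    min_segment: float = 8.0
    min_run_retained: float = 90.0
    min_runs: int = 2
    min_total: float = 300.0

    def __post_init__(self) -> None:
        for name in (
            "lpf_fd_threshold",
            "gev_dv_parameter",
            "eye_closure_min",
            "eye_gap_merge",
            "min_segment",
            "min_run_retained",
            "min_total",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.min_runs < 1:
            raise ValueError("min_runs must be >= 1")


@dataclass
class ConnectivityEstimate:
    """Run-level and participant-level ROI-pair partial correlations."""

    pair: str  # e.g. 'MGN-AC'
    run_values: list[float]
    nuisance_description: str = ""

    @property
    def participant_value(self) -> float:
        return float(np.mean(self.run_values))


# ---------------------------------------------------------------------------
# Normalization and detrending
# ---------------------------------------------------------------------------

def mode1000_normalize(series: VolumeSeries, brain: MaskVolume) -> VolumeSeries:
    """Scale so the modal in-brain intensity is 1000.

    The mode is the center of the fullest bin of a 100-bin histogram over
    all in-brain voxel values across time.
    """
    require_same_grid(series, brain)
    vals = np.asarray(series.data[brain.data], dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("brain mask is empty")
    counts, edges = np.histogram(vals, bins=100)
    k = int(np.argmax(counts))
    mode = 0.5 * (edges[k] + edges[k + 1])
    if mode <= 0:
        raise ValueError(f"non-positive modal value {mode}")
    return VolumeSeries(
        series.data.astype(float) * (1000.0 / mode), series.affine, series.tr_seconds
    )


def detrend_center(series: VolumeSeries) -> VolumeSeries:
    """Remove each voxel's least-squares linear trend (mean included)."""
    if series.n_volumes < 2:
        raise ValueError("need at least 2 volumes to detrend")
    data = signal.detrend(series.data.astype(float), axis=-1, type="linear")
    return VolumeSeries(data, series.affine, series.tr_seconds)


# ---------------------------------------------------------------------------
# Censoring
# ---------------------------------------------------------------------------

def motion_metric_censor(
    lpf_fd: np.ndarray,
    dv: np.ndarray | None,
    cfg: CensorConfig,
    dv_threshold: float | None = None,
) -> np.ndarray:
    """Keep-mask from precomputed per-volume motion metrics.

    Volumes with LPF-FD above the dataset-wide threshold are censored, as are
    volumes whose signal-fluctuation metric exceeds the run-wise threshold
    (``dv_threshold``; callers derive it from the GEV-DV parameter).
    """
    lpf_fd = np.asarray(lpf_fd, dtype=float)
    keep = lpf_fd <= cfg.lpf_fd_threshold
    if dv is not None and dv_threshold is not None:
        keep &= np.asarray(dv, dtype=float) <= dv_threshold
    return keep


def eye_closure_censor(
    closures: pd.DataFrame | list[tuple[float, float]],
    tr: float,
    n_volumes: int,
    min_closure: float = 3.0,
    gap_merge: float = 30.0,
) -> np.ndarray:
    """Keep-mask implementing the eye-closure censoring rules.

    Volumes overlapping a closure strictly longer than ``min_closure``
    seconds are censored; volumes between two such qualifying closures less
    than ``gap_merge`` seconds apart are censored too (the participant was
    likely drowsy throughout).  Volume t occupies [t*TR, (t+1)*TR).
    """
    if isinstance(closures, pd.DataFrame):
        intervals = list(zip(closures["onset"], closures["offset"]))
    else:
        intervals = list(closures)
    for onset, offset in intervals:
        if offset < onset:
            raise ValueError(f"malformed closure interval ({onset}, {offset})")
    qualifying = sorted(
        (float(a), float(b)) for a, b in intervals if (b - a) > min_closure
    )
    censor_spans = list(qualifying)
    for (a0, b0), (a1, b1) in zip(qualifying, qualifying[1:]):
        if a1 - b0 < gap_merge:
            censor_spans.append((b0, a1))

    starts = np.arange(n_volumes) * tr
    ends = starts + tr
    keep = np.ones(n_volumes, dtype=bool)
    for a, b in censor_spans:
        keep &= ~((starts < b) & (ends > a))
    return keep


def _segments(keep: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index ranges of contiguous kept volumes."""
    out = []
    in_seg = False
    for i, k in enumerate(keep):
        if k and not in_seg:
            start, in_seg = i, True
        elif not k and in_seg:
            out.append((start, i))
            in_seg = False
    if in_seg:
        out.append((start, len(keep)))
    return out


def apply_retention_rules(
    masks: list[np.ndarray],
    tr: float,
    cfg: CensorConfig | None = None,
) -> tuple[list[np.ndarray], list[bool], bool, dict]:
    """Prune short segments and apply run/participant retention thresholds.

    Kept segments shorter than ``min_segment`` seconds are censored; a run
    retaining less than ``min_run_retained`` seconds is dropped; the
    participant is dropped with fewer than ``min_runs`` surviving runs or
    less than ``min_total`` seconds across them.  Returns (pruned masks,
    run keep-decisions, participant keep-decision, report).
    """
    cfg = cfg or CensorConfig()
    pruned: list[np.ndarray] = []
    run_keep: list[bool] = []
    report: dict = {"runs": []}
    for keep in masks:
        keep = np.asarray(keep, dtype=bool).copy()
        for start, stop in _segments(keep):
            if (stop - start) * tr < cfg.min_segment:
                keep[start:stop] = False
        retained = float(keep.sum() * tr)
        ok = retained >= cfg.min_run_retained
        pruned.append(keep)
        run_keep.append(ok)
        report["runs"].append({"retained_seconds": retained, "kept": ok})
    total = sum(
        float(k.sum() * tr) for k, ok in zip(pruned, run_keep) if ok
    )
    n_kept = sum(run_keep)
    participant_keep = n_kept >= cfg.min_runs and total >= cfg.min_total
    report["total_retained_seconds"] = total
    report["n_runs_kept"] = n_kept
    report["participant_kept"] = participant_keep
    return pruned, run_keep, participant_keep, report


# ---------------------------------------------------------------------------
# Band-pass filtering
# ---------------------------------------------------------------------------

BAND_HZ = (0.009, 0.08)
EDGE_SECONDS = 22.0


def bandpass_filter(
    x: np.ndarray,
    tr: float,
    band: tuple[float, float] = BAND_HZ,
    order: int = 2,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    nyq = 0.5 / tr
    b, a = signal.butter(order, [band[0] / nyq, band[1] / nyq], btype="bandpass")
    return signal.filtfilt(b, a, np.asarray(x, dtype=float), axis=axis)


def edge_discard_count(tr: float, edge_seconds: float = EDGE_SECONDS) -> int:
    """Volumes discarded per run end after filtering: ceil(22 s / TR)."""
    return ceil(edge_seconds / tr)


def _interpolate_censored(data: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Linear interpolation over censored points; edges held at nearest."""
    t = np.arange(data.shape[-1])
    kept = np.flatnonzero(keep)
    if kept.size < 2:
        raise ValueError("need at least 2 retained volumes to interpolate")
    flat = data.reshape(-1, data.shape[-1])
    out = np.empty_like(flat, dtype=float)
    for i, row in enumerate(flat):
        out[i] = np.interp(t, kept, row[kept])
    return out.reshape(data.shape)


def bandpass_with_interpolation(
    data: np.ndarray | VolumeSeries,
    censor: np.ndarray,
    tr: float,
    band: tuple[float, float] = BAND_HZ,
    edge_seconds: float = EDGE_SECONDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Filter a run and restrict it to retained, non-edge volumes.

    Censored time points are replaced by linear interpolation before the
    zero-phase band-pass; after filtering, the first and last
    ``ceil(edge_seconds / TR)`` volumes are discarded and censored volumes
    dropped.  Returns ``(filtered data over kept volumes, kept volume
    indices)``; the time axis is last.
    """
    if isinstance(data, VolumeSeries):
        arr = data.data.astype(float)
    else:
        arr = np.asarray(data, dtype=float)
    censor = np.asarray(censor, dtype=bool)
    if censor.shape[0] != arr.shape[-1]:
        raise ValueError("censor mask length does not match volumes")
    interp = _interpolate_censored(arr, censor)
    filtered = bandpass_filter(interp, tr, band=band, axis=-1)
    n_edge = edge_discard_count(tr, edge_seconds)
    n = arr.shape[-1]
    keep = censor.copy()
    keep[:n_edge] = False
    keep[n - n_edge :] = False
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size < 2:
        raise ValueError(
            f"only {kept_idx.size} volumes remain after edge discard and censoring"
        )
    return filtered[..., kept_idx], kept_idx


# ---------------------------------------------------------------------------
# Nuisance and connectivity
# ---------------------------------------------------------------------------

def _derivative(x: np.ndarray) -> np.ndarray:
    """Backward difference along the first axis, first element 0."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def build_rsfc_nuisance(
    motion: np.ndarray | pd.DataFrame,
    wm: np.ndarray,
    csf: np.ndarray,
    tr: float,
    band: tuple[float, float] = BAND_HZ,
    filter_compartments: bool = False,
) -> np.ndarray:
    """28-column RSFC nuisance matrix for one run (full-length volumes).

    Columns: 6 band-pass filtered motion parameters, their squares, their
    backward-difference derivatives, the squares of those derivatives, then
    WM and its derivative, CSF and its derivative.  Squaring follows
    filtering and differentiation.  WM/CSF are unfiltered by default
    (``filter_compartments`` switches this).
    """
    mp = np.asarray(motion, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError(f"motion table must be (volumes, 6), got {mp.shape}")
    wm = np.asarray(wm, dtype=float).reshape(-1)
    csf = np.asarray(csf, dtype=float).reshape(-1)
    n = mp.shape[0]
    if wm.size != n or csf.size != n:
        raise ValueError("WM/CSF series length does not match the motion table")
    mp_f = bandpass_filter(mp, tr, band=band, axis=0)
    d_mp = _derivative(mp_f)
    if filter_compartments:
        wm = bandpass_filter(wm, tr, band=band)
        csf = bandpass_filter(csf, tr, band=band)
    cols = [
        mp_f,
        mp_f**2,
        d_mp,
        d_mp**2,
        wm[:, None],
        _derivative(wm[:, None]),
        csf[:, None],
        _derivative(csf[:, None]),
    ]
    return np.column_stack(cols)


def roi_pair_connectivity(
    seed_pairs: list[tuple[np.ndarray, np.ndarray]],
    target_pairs: list[tuple[np.ndarray, np.ndarray]],
    nuisance: list[np.ndarray | None],
    pair: str = "",
) -> ConnectivityEstimate:
    """Average hemispheric partial correlations into ROI-pair estimates.

    Each run contributes the mean of four partial correlations — left seed x
    left target, left x right, right x left, right x right — computed over
    that run's retained volumes; the participant value is the mean over runs.
    """
    if not (len(seed_pairs) == len(target_pairs) == len(nuisance)):
        raise ValueError("per-run lists must have equal length")
    run_values = []
    for (sl, sr), (tl, tr_series), nuis in zip(seed_pairs, target_pairs, nuisance):
        rs = [
            partial_correlation(s, t, nuis)
            for s in (sl, sr)
            for t in (tl, tr_series)
        ]
        run_values.append(float(np.mean(rs)))
    return ConnectivityEstimate(pair=pair, run_values=run_values)


SELECTIVITY_CONTRASTS = (
    ("MGN selectivity for AC", "MGN-AC", "MGN-VC"),
    ("AC selectivity for MGN", "MGN-AC", "LGN-AC"),
    ("LGN selectivity for VC", "LGN-VC", "LGN-AC"),
    ("VC selectivity for LGN", "LGN-VC", "MGN-VC"),
)


def selectivity_tests(
    table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """One-tailed paired t-tests of fROI selectivity, BH-FDR corrected.

    ``table`` has one row per participant and columns MGN-AC, MGN-VC,
    LGN-AC, LGN-VC.  Four directional contrasts are tested (greater-than),
    and p-values adjusted with the Benjamini-Hochberg step-up procedure.
    """
    required = {"MGN-AC", "MGN-VC", "LGN-AC", "LGN-VC"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"missing columns: {sorted(missing)}")
    if len(table) < 2:
        raise ValueError("need at least 2 participants")
    rows = []
    for name, greater, lesser in SELECTIVITY_CONTRASTS:
        diff = np.asarray(table[greater], float) - np.asarray(table[lesser], float)
        if diff.std(ddof=1) == 0.0:
            # degenerate paired sample: no variance in the differences
            t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
            p = 0.5 if diff.mean() == 0 else (0.0 if diff.mean() > 0 else 1.0)
        else:
            res = stats.ttest_rel(table[greater], table[lesser], alternative="greater")
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"contrast": name, "greater": greater, "lesser": lesser, "t": t, "p": p}
        )
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out


def seed_connectivity_map(
    seed_left: np.ndarray,
    seed_right: np.ndarray,
    rest: VolumeSeries | np.ndarray,
    nuisance: np.ndarray | None,
    brain: MaskVolume | None = None,
    affine: np.ndarray | None = None,
) -> VolumeImage:
    """Whole-brain partial-correlation seed map, hemispheres averaged.

    A map is computed per hemispheric seed against every (smoothed) voxel
    series, then the two maps are averaged voxelwise.  Difference maps
    between ROI sources are plain subtractions of the returned images.
    """
    if isinstance(rest, VolumeSeries):
        data = rest.data
        affine = rest.affine
    else:
        data = np.asarray(rest)
        if affine is None:
            raise ValueError("affine required when rest is a bare array")
    if brain is None:
        brain_data = np.ones(data.shape[:3], dtype=bool)
    else:
        brain_data = brain.data
    voxels = data[brain_data].T.astype(float)
    maps = []
    for seed in (seed_left, seed_right):
        seed = np.asarray(seed, float)
        if seed.std() == 0:
            raise ValueError("degenerate (constant) seed series")
        r, _ = partial_correlation_map(voxels, seed, nuisance)
        maps.append(r)
    mean_r = np.mean(maps, axis=0)
    out = np.zeros(data.shape[:3])
    out[brain_data] = mean_r
    return VolumeImage(out, affine)


def dice(a: MaskVolume, b: MaskVolume) -> float:
    """Dice-Sorensen overlap 2|A∩B| / (|A|+|B|); two empty masks give 0."""
    require_same_grid(a, b)
    total = a.size + b.size
    if total == 0:
        import warnings

        warnings.warn("Dice of two empty masks is defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * float((a.data & b.data).sum()) / total
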