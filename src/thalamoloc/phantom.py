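"""Synthetic phantom: labeled anatomy, task and rest BOLD, motion, eye logs.

The phantom emulates the data a sensory thalamic localizer session produces,
with known ground truth, so every downstream stage (GLM, cortex cluster
selection, TSR construction, coactivation fROI extraction, RSFC) can be
tested end to end without real scans.

Geometry is a deterministic set of ellipsoids on a RAS+ grid (2 mm isotropic
by default): per-hemisphere MGN, LGN, pulvinar, mediodorsal nucleus, putamen,
pallidum, hippocampus, choroid plexus, insular and parahippocampal white
matter, auditory-cortex (BA41/42 surrogate) and visual-cortex (BA17/18
surrogate) regions, a cortical gray-matter shell, deep white matter, a CSF
ventricle, and residual in-brain tissue.  Spatial relations honour the rules
the search-region construction depends on: LGN is lateral and superior to
MGN, and the pulvinar sits superior and posterior to both geniculi.

Task runs follow the clustered-sparse signal model: each acquired volume is
baseline x T1-decay(position in cluster) + condition amplitude (in
structures responsive to the trial's condition) + white noise.  The response
is a plateau sampled at acquisition — no HRF convolution — matching the
unconvolved regressors the sparse design calls for.

Rest runs plant band-limited latent signals with a chosen correlation
structure (MGN<->AC and LGN<->VC connectivity plus a weak cross-modal floor)
on top of WM/CSF/global nuisance signals and white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import LabelVolume, MaskVolume, VolumeSeries, dilate_mask
from .schedule import AUDITORY, VISUAL, TrialSchedule

__all__ = [
    "PhantomAnatomy",
    "TaskEffectSpec",
    "RestConnectivitySpec",
    "make_phantom_anatomy",
    "simulate_task_run",
    "simulate_rest_series",
    "simulate_rest_run",
    "simulate_motion_and_eyes",
    "PAIRED_STRUCTURES",
]

# Canonical geometry on a 48^3 grid: (dx from midline, y, z), ellipsoid radii.
# Paired structures are mirrored about the midline (left = smaller x = -world x).
_CANON = 48
_PAIRED_GEOMETRY: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    # name: ((dx, y, z), (rx, ry, rz))
    "MGN": ((7.0, 20.0, 21.5), (2.4, 2.4, 1.9)),
    "LGN": ((12.0, 21.0, 25.5), (2.2, 2.2, 2.0)),
    "AC": ((19.0, 22.0, 22.0), (2.5, 5.0, 4.0)),
    "VC": ((6.0, 7.0, 22.0), (3.0, 2.5, 4.0)),
    "pulvinar": ((5.0, 18.0, 27.5), (2.8, 2.8, 2.6)),
    "mediodorsal": ((5.0, 26.0, 28.0), (2.2, 2.2, 2.2)),
    "putamen": ((14.0, 28.0, 23.0), (2.5, 3.0, 3.0)),
    "pallidum": ((9.0, 27.0, 23.0), (2.0, 2.0, 2.0)),
    "hippocampus": ((12.0, 14.0, 19.0), (2.5, 3.0, 2.5)),
    "choroid_plexus": ((8.0, 15.0, 27.0), (2.0, 2.0, 2.0)),
    "insular_wm": ((17.0, 21.0, 24.0), (1.8, 3.0, 3.0)),
    "parahippocampal_wm": ((13.0, 10.0, 16.0), (2.5, 2.0, 2.0)),
}
PAIRED_STRUCTURES = tuple(_PAIRED_GEOMETRY)

_CSF_GEOMETRY = ((24.0, 27.0, 31.0), (2.0, 2.5, 2.0))
_SHELL_RADII = (17.5, 21.0)  # cortical GM annulus
_WM_RADIUS = 16.5
_BRAIN_RADIUS = 22.0


@dataclass
class PhantomAnatomy:
    """Labeled phantom anatomy plus bookkeeping."""

    labels: LabelVolume
    voxel_mm: float
    seed: int

    def mask(self, name: str) -> MaskVolume:
        return self.labels.mask(name)

    def brain_mask(self) -> MaskVolume:
        return MaskVolume(self.labels.data > 0, self.labels.affine)

    def gm_mask(self) -> MaskVolume:
        """Gray matter: cortical shell plus AC/VC surrogate regions."""
        return self.labels.union_mask(
            ["cortical_gm", "AC_left", "AC_right", "VC_left", "VC_right"]
        )


class ShapeTooSmallError(ValueError):
    """Grid too small to fit the phantom structures."""


def make_phantom_anatomy(
    shape: tuple[int, int, int] = (48, 48, 48),
    seed: int = 0,
    voxel_mm: float = 2.0,
) -> PhantomAnatomy:
    """Build the deterministic labeled phantom volume.

    The canonical geometry is defined on a 48^3 grid and scaled linearly to
    ``shape`` (minimum 32 per axis).  Earlier entries in the structure list
    win where ellipsoids would overlap, so labels are pairwise disjoint by
    construction.  At the default size each geniculus spans roughly 40-50
    voxels.  ``seed`` is recorded for provenance; the geometry itself is
    deterministic.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 32:
        raise ShapeTooSmallError(f"shape must be >= 32 per axis, got {shape}")
    scale = np.array(shape, dtype=float) / _CANON
    rscale = float(scale.min())
    mid = shape[0] / 2.0

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    data = np.zeros(shape, dtype=np.int32)
    table: dict[int, str] = {}
    next_id = 1

    def ellipsoid(center, radii) -> np.ndarray:
        cx, cy, cz = center
        rx, ry, rz = (max(r, 1.0) for r in radii)
        return (
            ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 + ((kk - cz) / rz) ** 2
        ) <= 1.0

    def assign(name: str, region: np.ndarray) -> None:
        nonlocal next_id
        region = region & (data == 0)
        if not region.any():
            raise ShapeTooSmallError(
                f"structure {name!r} is empty at shape {shape}"
            )
        data[region] = next_id
        table[next_id] = name
        next_id += 1

    for name, ((dx, y, z), radii) in _PAIRED_GEOMETRY.items():
        srad = tuple(r * rscale for r in radii)
        for hemi, sgn in (("left", -1), ("right", 1)):
            center = (
                mid + sgn * dx * scale[0],
                y * scale[1],
                z * scale[2],
            )
            assign(f"{name}_{hemi}", ellipsoid(center, srad))

    (ccx, ccy, ccz), cradii = _CSF_GEOMETRY
    assign(
        "csf",
        ellipsoid(
            (ccx * scale[0], ccy * scale[1], ccz * scale[2]),
            tuple(r * rscale for r in cradii),
        ),
    )

    center = np.array(shape) / 2.0
    r2 = (
        ((ii - center[0]) / scale[0]) ** 2
        + ((jj - center[1]) / scale[1]) ** 2
        + ((kk - center[2]) / scale[2]) ** 2
    )
    dist = np.sqrt(r2)  # distance in canonical-grid voxel units
    assign("cortical_gm", (dist >= _SHELL_RADII[0]) & (dist <= _SHELL_RADII[1]))
    assign("white_matter", dist <= _WM_RADIUS)
    assign("brain_other", dist <= _BRAIN_RADIUS)

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * center
    labels = LabelVolume(data, affine, table)
    return PhantomAnatomy(labels=labels, voxel_mm=voxel_mm, seed=seed)


# ---------------------------------------------------------------------------
# Task runs
# ---------------------------------------------------------------------------

def _default_amplitudes(structures, amplitude: float) -> dict[str, float]:
    return {name: amplitude for name in structures}


@dataclass
class TaskEffectSpec:
    """Planted task-response amplitudes and acquisition physics.

    Amplitudes are in raw signal units on top of ``baseline``; with the
    default baseline of 1000 the default amplitude of 20 is a 2% BOLD-like
    response.  ``t1_decay_factors`` multiply the baseline of successive
    volumes within an acquisition cluster, emulating non-steady-state
    T1 relaxation (the first volume is by definition undecayed).
    """

    auditory_amplitude: dict[str, float] = field(
        default_factory=lambda: _default_amplitudes(
            ("MGN_left", "MGN_right", "AC_left", "AC_right"), 20.0
        )
    )
    visual_amplitude: dict[str, float] = field(
        default_factory=lambda: _default_amplitudes(
            ("LGN_left", "LGN_right", "VC_left", "VC_right"), 20.0
        )
    )
    baseline: float = 1000.0
    t1_decay_factors: tuple[float, ...] = (1.0, 0.97, 0.95)
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if abs(self.t1_decay_factors[0] - 1.0) > 1e-12:
            raise ValueError("t1_decay_factors must start at 1 (first volume)")


def simulate_task_run(
    anatomy: PhantomAnatomy,
    schedule: TrialSchedule,
    spec: TaskEffectSpec | None = None,
    seed: int = 0,
) -> tuple[VolumeSeries, dict]:
    """Simulate one clustered-sparse task run.

    Every acquired volume is ``baseline * t1_decay(position)`` inside the
    brain, plus the condition amplitude in structures responsive to the
    trial's condition, plus Gaussian noise.  Returns the series and a ground
    truth dictionary holding the planted amplitudes.
    """
    spec = spec or TaskEffectSpec()
    if len(spec.t1_decay_factors) != schedule.params.volumes_per_cluster:
        raise ValueError(
            "t1_decay_factors length must equal volumes_per_cluster "
            f"({len(spec.t1_decay_factors)} vs {schedule.params.volumes_per_cluster})"
        )
    rng = np.random.default_rng(seed)
    brain = anatomy.brain_mask().data
    shape = anatomy.labels.data.shape
    n_vol = schedule.n_volumes
    data = np.zeros(shape + (n_vol,), dtype=np.float64)

    amp_masks = {
        AUDITORY: [
            (anatomy.mask(name).data, amp)
            for name, amp in spec.auditory_amplitude.items()
        ],
        VISUAL: [
            (anatomy.mask(name).data, amp)
            for name, amp in spec.visual_amplitude.items()
        ],
    }
    conditions = schedule.condition_per_volume()
    in_cluster = schedule.volume_in_cluster()
    for t in range(n_vol):
        frame = np.zeros(shape)
        frame[brain] = spec.baseline * spec.t1_decay_factors[in_cluster[t] - 1]
        for mask, amp in amp_masks.get(conditions[t], []):
            frame[mask] += amp
        if spec.noise_sd > 0:
            frame[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
        data[..., t] = frame

    series = VolumeSeries(data, anatomy.labels.affine, schedule.params.tr_seconds)
    truth = {
        "auditory_amplitude": dict(spec.auditory_amplitude),
        "visual_amplitude": dict(spec.visual_amplitude),
        "baseline": spec.baseline,
        "t1_decay_factors": list(spec.t1_decay_factors),
        "noise_sd": spec.noise_sd,
        "seed": int(seed),
        "schedule_seed": int(schedule.seed),
    }
    return series, truth


# ---------------------------------------------------------------------------
# Rest runs
# ---------------------------------------------------------------------------

@dataclass
class RestConnectivitySpec:
    """Planted resting-state latent-connectivity structure.

    ``r_mgn_ac`` and ``r_lgn_vc`` are the target Pearson correlations of the
    planted MGN<->AC and LGN<->VC latents; ``r_cross`` is the weak cross-modal
    floor between every other latent pair.  Nuisance amplitudes scale the
    WM, CSF, and global signals mixed into the data; ``noise_sd`` is white
    voxel noise on top of unit-variance latents.
    """

    r_mgn_ac: float = 0.5
    r_lgn_vc: float = 0.5
    r_cross: float = 0.05
    latent_amplitude: float = 1.0
    wm_amplitude: float = 0.5
    csf_amplitude: float = 0.5
    global_amplitude: float = 0.1
    noise_sd: float = 0.5
    baseline: float = 1000.0
    band_hz: tuple[float, float] = (0.009, 0.08)
    cortex_margin_voxels: int = 2

    def __post_init__(self) -> None:
        for name in ("r_mgn_ac", "r_lgn_vc", "r_cross"):
            if not abs(getattr(self, name)) < 1.0:
                raise ValueError(f"|{name}| must be < 1")

    def correlation_matrix(self) -> np.ndarray:
        """Target correlation of the (MGN, AC, LGN, VC) latents."""
        rc = self.r_cross
        R = np.array(
            [
                [1.0, self.r_mgn_ac, rc, rc],
                [self.r_mgn_ac, 1.0, rc, rc],
                [rc, rc, 1.0, self.r_lgn_vc],
                [rc, rc, self.r_lgn_vc, 1.0],
            ]
        )
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("target correlation matrix is not positive definite")
        return R


def _band_limited_noise(
    rng: np.random.Generator, n_series: int, n_volumes: int, tr: float, band
) -> np.ndarray:
    """Unit-variance noise with Fourier support restricted to ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not keep.any():
        keep = np.zeros_like(freqs, dtype=bool)
        keep[1] = True  # fall back to the slowest nonzero frequency
    spec = np.zeros((n_series, freqs.size), dtype=complex)
    n_keep = int(keep.sum())
    spec[:, keep] = rng.standard_normal((n_series, n_keep)) + 1j * rng.standard_normal(
        (n_series, n_keep)
    )
    x = np.fft.irfft(spec, n=n_volumes, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_rest_series(
    spec: RestConnectivitySpec,
    n_volumes: int,
    tr: float,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Generate the latent ROI and nuisance time series of one rest run.

    Returns unit-variance series ``mgn``, ``ac``, ``lgn``, ``vc`` whose
    empirical correlation matrix equals the spec's target exactly (the
    band-limited innovations are orthonormalized before Cholesky mixing),
    plus independent ``wm``, ``csf``, and ``global`` nuisance series.
    This is the statistical core that :func:`simulate_rest_run` scatters
    into a labeled volume.
    """
    if n_volumes < 8:
        raise ValueError("need at least 8 volumes for band-limited latents")
    rng = np.random.default_rng(seed)
    raw = _band_limited_noise(rng, 7, n_volumes, tr, spec.band_hz)
    Z = raw[:4]
    # Orthonormalize the innovations so the sample correlation is exact.
    Q, _ = np.linalg.qr(Z.T)
    Z = Q.T * np.sqrt(n_volumes)
    L = np.linalg.cholesky(spec.correlation_matrix())
    latents = L @ Z
    latents /= latents.std(axis=1, keepdims=True)
    return {
        "mgn": latents[0],
        "ac": latents[1],
        "lgn": latents[2],
        "vc": latents[3],
        "wm": raw[4],
        "csf": raw[5],
        "global": raw[6],
    }


def simulate_rest_run(
    anatomy: PhantomAnatomy,
    spec: RestConnectivitySpec | None = None,
    tr: float = 0.8,
    n_volumes: int = 300,
    seed: int = 0,
    dtype=np.float32,
) -> tuple[VolumeSeries, dict]:
    """Simulate one resting-state run with planted latent connectivity.

    Both hemispheres of a structure carry the same latent.  WM/CSF labels
    carry their nuisance series, the global signal is added to every in-brain
    voxel, and independent white noise tops every voxel.
    """
    spec = spec or RestConnectivitySpec()
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    rng = np.random.default_rng(seed)
    latents = simulate_rest_series(spec, n_volumes, tr, seed=seed)

    labels = anatomy.labels
    brain = anatomy.brain_mask().data
    shape = labels.data.shape
    data = np.zeros(shape + (n_volumes,), dtype=dtype)
    data[brain] = spec.baseline

    def add(mask_name: str, series: np.ndarray, amp: float, margin: int = 0) -> None:
        mask = labels.mask(mask_name)
        if margin:
            # the connectivity field of a cortical parcel extends past its
            # anatomical boundary; this keeps dilated a-priori ROIs informative
            mask = dilate_mask(mask, margin)
        region = mask.data & brain
        data[region] += (amp * series).astype(dtype)

    for hemi in ("left", "right"):
        add(f"MGN_{hemi}", latents["mgn"], spec.latent_amplitude)
        add(f"AC_{hemi}", latents["ac"], spec.latent_amplitude,
            spec.cortex_margin_voxels)
        add(f"LGN_{hemi}", latents["lgn"], spec.latent_amplitude)
        add(f"VC_{hemi}", latents["vc"], spec.latent_amplitude,
            spec.cortex_margin_voxels)
    add("white_matter", latents["wm"], spec.wm_amplitude)
    add("csf", latents["csf"], spec.csf_amplitude)
    data[brain] += (spec.global_amplitude * latents["global"]).astype(dtype)
    if spec.noise_sd > 0:
        n_brain = int(brain.sum())
        noise = rng.standard_normal((n_brain, n_volumes)).astype(dtype)
        data[brain] += spec.noise_sd * noise

    series = VolumeSeries(data, labels.affine, tr)
    truth = {
        "r_mgn_ac": spec.r_mgn_ac,
        "r_lgn_vc": spec.r_lgn_vc,
        "r_cross": spec.r_cross,
        "latent_amplitude": spec.latent_amplitude,
        "noise_sd": spec.noise_sd,
        "seed": int(seed),
    }
    return series, truth


# ---------------------------------------------------------------------------
# Motion and eye-closure logs
# ---------------------------------------------------------------------------

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


def simulate_motion_and_eyes(
    n_volumes: int,
    tr: float,
    seed: int = 0,
    translation_step_mm: float = 0.01,
    rotation_step_rad: float = 2e-4,
    amplitude_scale: float = 1.0,
    closures: list[tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate smooth random-walk motion traces and an eye-closure log.

    Motion is a Gaussian random walk per parameter (3 translations in mm,
    3 rotations in radians) scaled by ``amplitude_scale`` (0 gives all-zero
    traces).  ``closures`` is a list of (onset, offset) seconds appearing
    verbatim in the log; if None, a small random set is drawn.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes, 6))
    steps[:, :3] *= translation_step_mm
    steps[:, 3:] *= rotation_step_rad
    motion = np.cumsum(steps, axis=0) * amplitude_scale
    motion_df = pd.DataFrame(motion, columns=list(MOTION_COLUMNS))

    run_seconds = n_volumes * tr
    if closures is None:
        closures = []
        n_closures = int(rng.integers(0, 3))
        for _ in range(n_closures):
            onset = float(rng.uniform(0, max(run_seconds - 8.0, 1.0)))
            duration = float(rng.uniform(0.5, 6.0))
            closures.append((onset, min(onset + duration, run_seconds)))
        closures.sort()
    eye_df = pd.DataFrame(closures, columns=["onset", "offset"]).astype(float)
    return motion_df, eye_df
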