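"""Coactivation mapping within TSRs and MGN/LGN fROI extraction.

For every TSR voxel the task time series is partially correlated with the
AC (or VC) reference series, controlling for average WM, CSF, global GM, and
TSR-local WM signals, within-cluster volume-2/volume-3 indicators, and
per-run intercepts.  Maps are thresholded adaptively — the kept fraction is
``numerator / mean TSR size across hemispheres`` (numerator 32 for MGN, 20
for LGN), so roughly that many voxels survive per hemisphere — voxels kept
by both the AC and VC maps of a TSR are removed from both, and the largest
remaining contiguous cluster becomes the fROI.  Automated QC flags stand in
for manual visual review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from ._stats import partial_correlation_map
from .imaging import (
    MaskVolume,
    VolumeSeries,
    centroid_world,
    connected_components,
    require_same_grid,
)

__all__ = [
    "CoactivationMap",
    "ThresholdConfig",
    "FroiResult",
    "coactivation_map",
    "adaptive_threshold",
    "remove_cross_modal_overlap",
    "extract_froi",
    "qc_flags",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Adaptive-threshold numerators (voxels kept per hemisphere, roughly)."""

    mgn_numerator: float = 32.0
    lgn_numerator: float = 20.0

    def __post_init__(self) -> None:
        if self.mgn_numerator <= 0 or self.lgn_numerator <= 0:
            raise ValueError("threshold numerators must be positive")

    def numerator(self, nucleus: str) -> float:
        return {"MGN": self.mgn_numerator, "LGN": self.lgn_numerator}[nucleus]


@dataclass
class CoactivationMap:
    """Partial-correlation values over one TSR against one cortex target."""

    values: np.ndarray  # 3D, zero outside the TSR
    tsr: MaskVolume
    cortex_target: str  # 'AC' or 'VC'
    degenerate: int = 0  # count of voxels with constant residuals (r set to 0)

    @property
    def affine(self) -> np.ndarray:
        return self.tsr.affine


@dataclass
class FroiResult:
    """Final per-hemisphere fROIs with sizes, QC flags, and provenance."""

    mgn_left: MaskVolume
    mgn_right: MaskVolume
    lgn_left: MaskVolume
    lgn_right: MaskVolume
    qc: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "mgn_left": self.mgn_left.size,
            "mgn_right": self.mgn_right.size,
            "lgn_left": self.lgn_left.size,
            "lgn_right": self.lgn_right.size,
        }

    def mask(self, nucleus: str, hemisphere: str) -> MaskVolume:
        return getattr(self, f"{nucleus.lower()}_{hemisphere.lower()}")


def coactivation_map(
    task_series: VolumeSeries,
    tsr: MaskVolume,
    cortex_series: np.ndarray,
    nuisance: np.ndarray | None,
    cortex_target: str = "",
) -> CoactivationMap:
    """Partial correlation of each TSR voxel with a cortex reference series.

    Both the voxel and reference series are residualized on the nuisance
    matrix (plus an intercept) before correlating.  Voxels whose residual is
    constant are set to r = 0 and counted in ``degenerate``.
    """
    require_same_grid(task_series, tsr)
    cortex_series = np.asarray(cortex_series, float)
    if cortex_series.shape[0] != task_series.n_volumes:
        raise ValueError("cortex series length does not match series volumes")
    voxels = task_series.data[tsr.data].T.astype(float)  # (T, V)
    r, degen = partial_correlation_map(voxels, cortex_series, nuisance)
    values = np.zeros(task_series.data.shape[:3])
    values[tsr.data] = r
    return CoactivationMap(
        values=values,
        tsr=tsr,
        cortex_target=cortex_target,
        degenerate=int(degen.sum()),
    )


def adaptive_threshold(
    cmap: CoactivationMap,
    tsr_sizes: tuple[int, int],
    numerator: float,
) -> MaskVolume:
    """Keep the top-correlated TSR voxels at the participant-adaptive rate.

    The kept fraction is ``numerator / mean(tsr_sizes)`` (capped at 1), and
    this hemisphere keeps ``ceil(fraction * N)`` of its N TSR voxels, ranked
    by r with ties broken by r and then linear voxel index.
    """
    if numerator <= 0:
        raise ValueError("numerator must be positive")
    n_hemi = cmap.tsr.size
    if n_hemi == 0:
        raise ValueError("empty coactivation map")
    mean_n = float(np.mean(tsr_sizes))
    fraction = min(1.0, numerator / mean_n)
    n_keep = min(n_hemi, ceil(fraction * n_hemi))
    flat_idx = np.flatnonzero(cmap.tsr.data.ravel())
    vals = cmap.values.ravel()[flat_idx]
    order = np.lexsort((flat_idx, -vals))
    kept = flat_idx[order[:n_keep]]
    out = np.zeros(cmap.values.size, dtype=bool)
    out[kept] = True
    return MaskVolume(out.reshape(cmap.values.shape), cmap.affine)


def remove_cross_modal_overlap(
    ac_mask: MaskVolume, vc_mask: MaskVolume
) -> tuple[MaskVolume, MaskVolume]:
    """Remove voxels kept by both the AC and VC maps of a TSR from both."""
    require_same_grid(ac_mask, vc_mask)
    overlap = ac_mask.data & vc_mask.data
    return (
        MaskVolume(ac_mask.data & ~overlap, ac_mask.affine),
        MaskVolume(vc_mask.data & ~overlap, vc_mask.affine),
    )


def extract_froi(
    thresholded: MaskVolume, connectivity: int = 18
) -> tuple[MaskVolume, list[str]]:
    """Largest contiguous cluster of a thresholded map; empty input flags."""
    components = connected_components(thresholded, connectivity)
    if not components:
        return (
            MaskVolume(np.zeros(thresholded.shape, dtype=bool), thresholded.affine),
            ["empty_froi"],
        )
    return components[0], []


def qc_flags(result: FroiResult, asymmetry_bound: float = 3.0) -> list[str]:
    """Automated anatomical-plausibility surrogates for manual fROI review.

    Flags: empty fROIs; an LGN centroid inferior to or medial to the
    ipsilateral MGN centroid; left/right size asymmetry of either nucleus
    beyond ``asymmetry_bound``; MGN/LGN fROI overlap.
    """
    flags: list[str] = []
    sizes = result.sizes
    for name, n in sizes.items():
        if n == 0:
            flags.append(f"empty_{name}")

    for hemi in ("left", "right"):
        mgn = result.mask("MGN", hemi)
        lgn = result.mask("LGN", hemi)
        if mgn.size and lgn.size:
            c_mgn = centroid_world(mgn)
            c_lgn = centroid_world(lgn)
            if c_lgn[2] < c_mgn[2]:
                flags.append(f"lgn_inferior_to_mgn_{hemi}")
            if abs(c_lgn[0]) < abs(c_mgn[0]):
                flags.append(f"lgn_medial_to_mgn_{hemi}")
        if mgn.size and lgn.size and (mgn.data & lgn.data).any():
            flags.append(f"mgn_lgn_overlap_{hemi}")

    for nucleus in ("mgn", "lgn"):
        left, right = sizes[f"{nucleus}_left"], sizes[f"{nucleus}_right"]
        if left and right:
            ratio = max(left, right) / min(left, right)
            if ratio > asymmetry_bound:
                flags.append(f"asymmetric_{nucleus}")
    return flags
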