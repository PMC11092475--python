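"""Selection of maximally responsive AC/VC cortex clusters and their series.

Within each hemisphere's Brodmann-style search mask (BA41/42 for auditory
cortex, BA17/18 for visual cortex, dilated once), the top 10% of
[Auditory - Visual] contrast voxels (bottom 10% for VC) are kept, clusters
under 10 contiguous voxels dropped, and the cluster containing the
greatest-magnitude surviving contrast value is used for time-series
extraction.  Hemispheric series are averaged spatially and then across
hemispheres into one AC and one VC reference series.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .imaging import (
    LabelVolume,
    MaskVolume,
    VolumeImage,
    VolumeSeries,
    connected_components,
    dilate_mask,
    require_same_grid,
)

__all__ = [
    "CortexSearchMasks",
    "CortexCluster",
    "build_cortex_search_masks",
    "select_cortex_cluster",
    "extract_cluster_series",
    "average_hemisphere_series",
    "NoClusterError",
]


class NoClusterError(RuntimeError):
    """No suprathreshold cluster of the minimum size survived (QC failure)."""


@dataclass
class CortexSearchMasks:
    ac_left: MaskVolume
    ac_right: MaskVolume
    vc_left: MaskVolume
    vc_right: MaskVolume

    def get(self, modality: str, hemisphere: str) -> MaskVolume:
        return getattr(self, f"{modality.lower()}_{hemisphere.lower()}")


@dataclass
class CortexCluster:
    mask: MaskVolume
    peak_value: float
    hemisphere: str
    modality: str


def build_cortex_search_masks(
    ba_labels: LabelVolume,
    ac_names: dict[str, list[str]] | None = None,
    vc_names: dict[str, list[str]] | None = None,
) -> CortexSearchMasks:
    """Union the BA-style cortex labels per modality/hemisphere, dilated once.

    ``ac_names``/``vc_names`` map hemisphere -> label names; defaults match
    the phantom's AC/VC surrogate regions.
    """
    ac_names = ac_names or {"left": ["AC_left"], "right": ["AC_right"]}
    vc_names = vc_names or {"left": ["VC_left"], "right": ["VC_right"]}

    def build(names: list[str]) -> MaskVolume:
        for n in names:
            if n not in ba_labels.name_table:
                raise KeyError(f"label {n!r} missing from label volume")
        return dilate_mask(ba_labels.union_mask(names), 1)

    return CortexSearchMasks(
        ac_left=build(ac_names["left"]),
        ac_right=build(ac_names["right"]),
        vc_left=build(vc_names["left"]),
        vc_right=build(vc_names["right"]),
    )


def _top_fraction_mask(
    values: np.ndarray,
    search: np.ndarray,
    tail: str,
    fraction: float,
) -> np.ndarray:
    """Keep the ceil(fraction*N) most extreme in-mask voxels of one tail.

    Ties at the cutoff are broken by contrast value and then by linear voxel
    index, so the kept count is exact and deterministic.
    """
    flat_idx = np.flatnonzero(search.ravel())
    vals = values.ravel()[flat_idx]
    n_keep = ceil(fraction * flat_idx.size)
    key = -vals if tail == "upper" else vals
    order = np.lexsort((flat_idx, key))
    kept = flat_idx[order[:n_keep]]
    out = np.zeros(values.size, dtype=bool)
    out[kept] = True
    return out.reshape(values.shape)


def select_cortex_cluster(
    contrast: VolumeImage,
    search: MaskVolume,
    tail: str,
    fraction: float = 0.10,
    min_cluster: int = 10,
    connectivity: int = 18,
    hemisphere: str = "",
    modality: str = "",
) -> CortexCluster:
    """Select the peak cortex cluster within one search mask.

    ``tail='upper'`` selects auditory-dominant voxels of the A-V contrast,
    ``tail='lower'`` visual-dominant.  After thresholding, components smaller
    than ``min_cluster`` voxels are dropped; the returned cluster is the one
    containing the largest-magnitude surviving contrast value.
    """
    require_same_grid(contrast, search)
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if search.size == 0:
        raise ValueError("search mask is empty")
    thresholded = _top_fraction_mask(contrast.data, search.data, tail, fraction)
    components = [
        c
        for c in connected_components(MaskVolume(thresholded, search.affine), connectivity)
        if c.size >= min_cluster
    ]
    if not components:
        raise NoClusterError(
            f"no suprathreshold cluster of >= {min_cluster} voxels in "
            f"{modality or 'cortex'} {hemisphere or ''} search mask".strip()
        )
    surviving = np.zeros(thresholded.shape, dtype=bool)
    for c in components:
        surviving |= c.data
    mags = np.abs(contrast.data) * surviving
    peak_idx = np.unravel_index(int(np.argmax(mags)), mags.shape)
    peak_value = float(contrast.data[peak_idx])
    for c in components:
        if c.data[peak_idx]:
            return CortexCluster(
                mask=c, peak_value=peak_value, hemisphere=hemisphere, modality=modality
            )
    raise AssertionError("peak voxel not contained in any surviving component")


def extract_cluster_series(series: VolumeSeries, cluster: CortexCluster) -> np.ndarray:
    """Spatial mean time series over one cluster."""
    require_same_grid(series, cluster.mask)
    if cluster.mask.size == 0:
        raise ValueError("cluster mask is empty")
    return series.data[cluster.mask.data].mean(axis=0)


def average_hemisphere_series(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Unweighted mean of the two hemispheric series."""
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    if left.shape != right.shape:
        raise ValueError("hemisphere series lengths differ")
    return (left + right) / 2.0
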