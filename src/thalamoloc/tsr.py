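"""Participant-specific thalamic search regions (TSR) and nuisance masks.

The MGN-TSR dilates the segmented MGN by 3 voxels (the smaller nucleus needs
the larger search space) and the LGN-TSR dilates LGN by 1.  Voxels belonging
to surrounding structures are then removed: cortical gray matter,
parahippocampal WM, and hippocampus undilated; mediodorsal nucleus, insular
WM, choroid plexus, pulvinar, putamen, and pallidum each dilated by 1 (label
sources for thalamic nuclei and whole-brain parcellation are merged).  The
posterior-most two occupied slices of each TSR are dropped to stay clear of
midbrain, and — for the MGN-TSR only — voxels superior to the inferior-most
pulvinar slice (either hemisphere, undilated thalamic-nuclei label) are
removed to confine the search to inferior posterior thalamus.

Rule order: structure subtraction, posterior trim, pulvinar-inferior
constraint.  Each rule logs the voxels it removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import (
    LabelVolume,
    MaskVolume,
    dilate_mask,
    erode_compartment_mask,
    require_same_grid,
    world_axis,
)
from scipy import ndimage

__all__ = [
    "TsrNameConfig",
    "TsrResult",
    "build_tsr",
    "build_local_wm_mask",
    "build_global_gm_mask",
    "TsrConstructionError",
]

DILATE_ITERATIONS = {"MGN": 3, "LGN": 1}


class TsrConstructionError(RuntimeError):
    """A TSR came out empty; the participant fails localization."""


@dataclass
class TsrNameConfig:
    """Label names used to resolve seeds and exclusion structures.

    Paired names (one per hemisphere) are given as base names; ``_left`` /
    ``_right`` suffixes are appended.  Defaults match the phantom's label
    table; callers with FreeSurfer/THOMAS-style tables supply their own.
    """

    exclude_undilated: tuple[str, ...] = (
        "cortical_gm",
        "parahippocampal_wm",
        "hippocampus",
    )
    exclude_dilated: tuple[str, ...] = (
        "mediodorsal",
        "insular_wm",
        "choroid_plexus",
        "pulvinar",
        "putamen",
        "pallidum",
    )
    pulvinar: str = "pulvinar"
    gm_names: tuple[str, ...] = ("cortical_gm", "AC", "VC")
    wm_name: str = "white_matter"


@dataclass
class TsrResult:
    """Per-hemisphere TSR masks plus a per-rule removal log."""

    masks: dict[str, MaskVolume]  # 'left' / 'right'
    nucleus: str
    provenance: dict[str, dict[str, int]] = field(default_factory=dict)


def _resolve_masks(volumes: list[LabelVolume], base: str) -> np.ndarray:
    """Union of every label matching ``base`` or ``base_{left,right}``."""
    out = None
    candidates = (base, f"{base}_left", f"{base}_right")
    for vol in volumes:
        for name in candidates:
            if name in vol.name_table:
                m = vol.mask(name).data
                out = m if out is None else (out | m)
    return out


def build_tsr(
    thalamic_labels: LabelVolume,
    parcellation: LabelVolume,
    nucleus: str,
    names: TsrNameConfig | None = None,
) -> TsrResult:
    """Construct the per-hemisphere MGN or LGN thalamic search regions."""
    if nucleus not in DILATE_ITERATIONS:
        raise ValueError(f"nucleus must be MGN or LGN, got {nucleus!r}")
    names = names or TsrNameConfig()
    require_same_grid(thalamic_labels, parcellation)
    sources = [thalamic_labels, parcellation]
    affine = thalamic_labels.affine

    excl_und = np.zeros(thalamic_labels.data.shape, dtype=bool)
    for base in names.exclude_undilated:
        m = _resolve_masks(sources, base)
        if m is not None:
            excl_und |= m
    excl_dil = np.zeros_like(excl_und)
    for base in names.exclude_dilated:
        m = _resolve_masks(sources, base)
        if m is not None:
            excl_dil |= dilate_mask(MaskVolume(m, affine), 1).data
    exclusion = excl_und | excl_dil

    pulvinar = _resolve_masks([thalamic_labels], names.pulvinar)
    if nucleus == "MGN" and pulvinar is None:
        raise TsrConstructionError("pulvinar label required for the MGN-TSR rule")

    y_axis, y_sign = world_axis(affine, "anterior")
    z_axis, z_sign = world_axis(affine, "superior")

    result = TsrResult(masks={}, nucleus=nucleus)
    for hemi in ("left", "right"):
        seed_name = f"{nucleus}_{hemi}"
        if seed_name not in thalamic_labels.name_table:
            raise TsrConstructionError(f"seed label {seed_name!r} not found")
        seed = thalamic_labels.mask(seed_name)
        tsr = dilate_mask(seed, DILATE_ITERATIONS[nucleus]).data
        log: dict[str, int] = {"dilated_seed": int(tsr.sum())}

        removed = tsr & exclusion
        tsr = tsr & ~exclusion
        log["surrounding_structures"] = int(removed.sum())

        # posterior-most 2 occupied slices of this TSR
        axis_other = tuple(a for a in range(3) if a != y_axis)
        occupied = np.flatnonzero(tsr.any(axis=axis_other))
        posterior = occupied[:2] if y_sign > 0 else occupied[-2:]
        slicer = [slice(None)] * 3
        removed_n = 0
        for idx in posterior:
            slicer[y_axis] = idx
            removed_n += int(tsr[tuple(slicer)].sum())
            tsr[tuple(slicer)] = False
        log["posterior_trim"] = removed_n

        if nucleus == "MGN":
            axis_other_z = tuple(a for a in range(3) if a != z_axis)
            pul_slices = np.flatnonzero(pulvinar.any(axis=axis_other_z))
            inferior_most = pul_slices[0] if z_sign > 0 else pul_slices[-1]
            zi = np.arange(tsr.shape[z_axis])
            superior = (
                zi > inferior_most if z_sign > 0 else zi < inferior_most
            )
            shape_b = [1, 1, 1]
            shape_b[z_axis] = tsr.shape[z_axis]
            sup_mask = np.broadcast_to(superior.reshape(shape_b), tsr.shape)
            log["superior_to_pulvinar"] = int((tsr & sup_mask).sum())
            tsr = tsr & ~sup_mask

        if not tsr.any():
            raise TsrConstructionError(
                f"{nucleus}-TSR {hemi} is empty after exclusion rules "
                f"(removal log: {log})"
            )
        log["final"] = int(tsr.sum())
        result.masks[hemi] = MaskVolume(tsr, affine)
        result.provenance[hemi] = log
    return result


def build_local_wm_mask(tsr: MaskVolume, wm: MaskVolume) -> MaskVolume:
    """WM voxels between 1 and 5 voxels from the TSR in any direction.

    'Any direction' is read as Chebyshev (chessboard) distance, i.e. the
    shell ``dilate(tsr, 5) \\ tsr`` intersected with WM.  Averaged from
    unsmoothed data downstream, this supplies the TSR-local WM nuisance.
    """
    require_same_grid(tsr, wm)
    shell = dilate_mask(tsr, 5).data & ~tsr.data
    return MaskVolume(shell & wm.data, tsr.affine)


def build_global_gm_mask(
    parcellation: LabelVolume, gm_names: tuple[str, ...] = ("cortical_gm", "AC", "VC")
) -> MaskVolume:
    """Union of gray-matter labels eroded once (3x3x3 element)."""
    gm = None
    for base in gm_names:
        m = _resolve_masks([parcellation], base)
        if m is not None:
            gm = m if gm is None else (gm | m)
    if gm is None or not gm.any():
        raise ValueError(f"no gray-matter labels found among {gm_names}")
    eroded = ndimage.binary_erosion(gm, structure=np.ones((3, 3, 3), dtype=bool))
    if not eroded.any():
        raise ValueError("gray-matter mask is empty after one erosion")
    return MaskVolume(eroded, parcellation.affine)


def compartment_nuisance_mask(parcellation: LabelVolume, name: str) -> MaskVolume:
    """Iteratively eroded WM or CSF compartment mask for nuisance extraction."""
    mask = _resolve_masks([parcellation], name)
    if mask is None:
        raise KeyError(f"label {name!r} not found")
    return erode_compartment_mask(MaskVolume(mask, parcellation.affine))
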