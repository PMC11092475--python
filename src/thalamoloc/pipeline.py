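"""End-to-end orchestration of the localizer and RSFC stages.

`run_localizer` executes the task-analysis chain — smoothing, compartment
nuisance extraction, GLM and A-V contrast, cortex cluster selection, TSR
construction, coactivation mapping, adaptive thresholding, cross-modal
overlap removal, fROI extraction, QC — on in-memory task runs.  `run_rsfc`
executes resting-state post-processing and ROI-pair connectivity for one
participant.  The CLI wraps these with disk I/O and provenance records.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import cortex as cortex_mod
from . import froi as froi_mod
from . import rsfc as rsfc_mod
from . import tsr as tsr_mod
from .glm import build_design_matrix, contrast_auditory_minus_visual, fit_glm
from .imaging import (
    LabelVolume,
    MaskVolume,
    VolumeImage,
    VolumeSeries,
    dilate_mask,
    smooth_series,
)
from .schedule import TrialSchedule

__all__ = [
    "PipelineConfig",
    "TaskRun",
    "RestRun",
    "LocalizerOutput",
    "run_localizer",
    "run_rsfc",
    "build_primary_sensory_rois",
    "MinimumRunsError",
]


class MinimumRunsError(ValueError):
    """Fewer task runs than the protocol minimum of two."""


@dataclass(frozen=True)
class PipelineConfig:
    smoothing_fwhm_mm: float = 4.0
    min_task_runs: int = 2
    cluster_connectivity: int = 18
    cortex_fraction: float = 0.10
    cortex_min_cluster: int = 10
    mgn_numerator: float = 32.0
    lgn_numerator: float = 20.0
    asymmetry_bound: float = 3.0
    censor: rsfc_mod.CensorConfig = field(default_factory=rsfc_mod.CensorConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class TaskRun:
    series: VolumeSeries
    schedule: TrialSchedule
    motion: pd.DataFrame


@dataclass
class RestRun:
    series: VolumeSeries
    motion: pd.DataFrame
    eye_closures: pd.DataFrame | None = None
    censor: np.ndarray | None = None  # precomputed keep-mask, optional


@dataclass
class LocalizerOutput:
    froi: froi_mod.FroiResult
    contrast: VolumeImage
    tsrs: dict[str, tsr_mod.TsrResult]
    clusters: dict[str, cortex_mod.CortexCluster]
    ac_series: np.ndarray
    vc_series: np.ndarray
    provenance: dict


def _roi_series(data: np.ndarray, mask: MaskVolume) -> np.ndarray:
    if mask.size == 0:
        raise ValueError("cannot extract a series from an empty mask")
    return data[mask.data].mean(axis=0)


def run_localizer(
    thalamic_labels: LabelVolume,
    parcellation: LabelVolume,
    runs: list[TaskRun],
    config: PipelineConfig | None = None,
    tsr_names: tsr_mod.TsrNameConfig | None = None,
) -> LocalizerOutput:
    """Derive participant-specific MGN and LGN fROIs from task runs."""
    config = config or PipelineConfig()
    if len(runs) < config.min_task_runs:
        raise MinimumRunsError(
            f"{len(runs)} task run(s) given; the protocol requires at least "
            f"{config.min_task_runs}"
        )
    names = tsr_names or tsr_mod.TsrNameConfig()
    schedules = [r.schedule for r in runs]
    motions = [np.asarray(r.motion, dtype=float) for r in runs]

    smoothed = [smooth_series(r.series, config.smoothing_fwhm_mm) for r in runs]
    wm_mask = tsr_mod.compartment_nuisance_mask(parcellation, names.wm_name)
    csf_mask = tsr_mod.compartment_nuisance_mask(parcellation, "csf")
    wm_series = [_roi_series(r.series.data, wm_mask) for r in runs]
    csf_series = [_roi_series(r.series.data, csf_mask) for r in runs]

    design = build_design_matrix(schedules, motions, wm_series, csf_series)
    concat_sm = VolumeSeries(
        np.concatenate([s.data for s in smoothed], axis=-1),
        runs[0].series.affine,
        runs[0].series.tr_seconds,
    )
    brain = MaskVolume(
        (thalamic_labels.data > 0) | (parcellation.data > 0), parcellation.affine
    )
    betas = fit_glm(concat_sm, design, brain)
    contrast = contrast_auditory_minus_visual(betas)

    search = cortex_mod.build_cortex_search_masks(parcellation)
    clusters: dict[str, cortex_mod.CortexCluster] = {}
    hemi_series: dict[str, np.ndarray] = {}
    for modality, tail in (("AC", "upper"), ("VC", "lower")):
        for hemi in ("left", "right"):
            cluster = cortex_mod.select_cortex_cluster(
                contrast,
                search.get(modality, hemi),
                tail=tail,
                fraction=config.cortex_fraction,
                min_cluster=config.cortex_min_cluster,
                connectivity=config.cluster_connectivity,
                hemisphere=hemi,
                modality=modality,
            )
            clusters[f"{modality}_{hemi}"] = cluster
            hemi_series[f"{modality}_{hemi}"] = np.concatenate(
                [cortex_mod.extract_cluster_series(s, cluster) for s in smoothed]
            )
    ac_series = cortex_mod.average_hemisphere_series(
        hemi_series["AC_left"], hemi_series["AC_right"]
    )
    vc_series = cortex_mod.average_hemisphere_series(
        hemi_series["VC_left"], hemi_series["VC_right"]
    )

    tsrs = {
        nucleus: tsr_mod.build_tsr(thalamic_labels, parcellation, nucleus, names)
        for nucleus in ("MGN", "LGN")
    }
    gm_mask = tsr_mod.build_global_gm_mask(parcellation, names.gm_names)

    # shared nuisance ingredients, concatenated across runs
    wm_cat = np.concatenate(wm_series)
    csf_cat = np.concatenate(csf_series)
    gm_cat = np.concatenate([_roi_series(r.series.data, gm_mask) for r in runs])
    vol2 = np.concatenate(
        [(s.volume_in_cluster() == 2).astype(float) for s in schedules]
    )
    vol3 = np.concatenate(
        [(s.volume_in_cluster() == 3).astype(float) for s in schedules]
    )
    n_per_run = [s.n_volumes for s in schedules]
    run_dummies = np.zeros((sum(n_per_run), len(runs)))
    row = 0
    for r, n in enumerate(n_per_run):
        run_dummies[row : row + n, r] = 1.0
        row += n

    thresholds = froi_mod.ThresholdConfig(
        mgn_numerator=config.mgn_numerator, lgn_numerator=config.lgn_numerator
    )
    froi_masks: dict[str, MaskVolume] = {}
    qc: list[str] = []
    prov: dict = {"tsr": {}, "threshold": {}, "config_hash": config.hash()}
    for nucleus, target_series, target_name in (
        ("MGN", ac_series, "AC"),
        ("LGN", vc_series, "VC"),
    ):
        tsr_pair = tsrs[nucleus]
        sizes = (tsr_pair.masks["left"].size, tsr_pair.masks["right"].size)
        prov["tsr"][nucleus] = tsr_pair.provenance
        other_series = vc_series if target_name == "AC" else ac_series
        for hemi in ("left", "right"):
            tsr_mask = tsr_pair.masks[hemi]
            local_wm = tsr_mod.build_local_wm_mask(tsr_mask, wm_mask)
            local_wm_cat = np.concatenate(
                [_roi_series(r.series.data, local_wm) for r in runs]
            )
            nuisance = np.column_stack(
                [wm_cat, csf_cat, gm_cat, local_wm_cat, vol2, vol3, run_dummies]
            )
            cmap_target = froi_mod.coactivation_map(
                concat_sm, tsr_mask, target_series, nuisance, target_name
            )
            cmap_other = froi_mod.coactivation_map(
                concat_sm,
                tsr_mask,
                other_series,
                nuisance,
                "VC" if target_name == "AC" else "AC",
            )
            numerator = thresholds.numerator(nucleus)
            kept_target = froi_mod.adaptive_threshold(cmap_target, sizes, numerator)
            kept_other = froi_mod.adaptive_threshold(cmap_other, sizes, numerator)
            if target_name == "AC":
                kept_ac, kept_vc = kept_target, kept_other
            else:
                kept_ac, kept_vc = kept_other, kept_target
            kept_ac, kept_vc = froi_mod.remove_cross_modal_overlap(kept_ac, kept_vc)
            kept = kept_ac if target_name == "AC" else kept_vc
            froi, flags = froi_mod.extract_froi(kept, config.cluster_connectivity)
            froi_masks[f"{nucleus.lower()}_{hemi}"] = froi
            qc += [f"{f}_{nucleus.lower()}_{hemi}" for f in flags]
            prov["threshold"][f"{nucleus}_{hemi}"] = {
                "tsr_size": tsr_mask.size,
                "numerator": numerator,
                "kept": int(kept.size),
                "froi_size": froi.size,
            }

    result = froi_mod.FroiResult(
        mgn_left=froi_masks["mgn_left"],
        mgn_right=froi_masks["mgn_right"],
        lgn_left=froi_masks["lgn_left"],
        lgn_right=froi_masks["lgn_right"],
        provenance=prov,
    )
    result.qc = qc + froi_mod.qc_flags(result, config.asymmetry_bound)
    return LocalizerOutput(
        froi=result,
        contrast=contrast,
        tsrs=tsrs,
        clusters=clusters,
        ac_series=ac_series,
        vc_series=vc_series,
        provenance=prov,
    )


def build_primary_sensory_rois(
    parcellation: LabelVolume,
) -> dict[str, MaskVolume]:
    """Anatomy-based primary AC and VC ROIs, independent of the task.

    AC: the transverse-temporal-style auditory parcel dilated once.  VC: the
    pericalcarine-style visual parcel dilated once, restricted to gray
    matter, then dilated twice more.
    """
    gm = None
    for base in ("cortical_gm", "AC", "VC"):
        m = tsr_mod._resolve_masks([parcellation], base)
        if m is not None:
            gm = m if gm is None else (gm | m)
    out = {}
    for hemi in ("left", "right"):
        ac = parcellation.mask(f"AC_{hemi}")
        out[f"AC_{hemi}"] = dilate_mask(ac, 1)
        vc = dilate_mask(parcellation.mask(f"VC_{hemi}"), 1)
        vc = MaskVolume(vc.data & gm, parcellation.affine)
        out[f"VC_{hemi}"] = dilate_mask(vc, 2)
    return out


def run_rsfc(
    parcellation: LabelVolume,
    froi: froi_mod.FroiResult,
    runs: list[RestRun],
    config: PipelineConfig | None = None,
    wm_name: str = "white_matter",
    csf_name: str = "csf",
) -> dict:
    """Resting-state connectivity of the localized nuclei for one participant.

    Applies normalization, detrending, censoring, retention rules, and
    filtering, then estimates MGN-AC, MGN-VC, LGN-AC, and LGN-VC ROI-pair
    partial correlations.  Returns a report dict with per-pair estimates,
    retention decisions, and exclusions (never silently dropped).
    """
    config = config or PipelineConfig()
    cfg = config.censor
    brain = MaskVolume(parcellation.data > 0, parcellation.affine)
    wm_mask = tsr_mod.compartment_nuisance_mask(parcellation, wm_name)
    csf_mask = tsr_mod.compartment_nuisance_mask(parcellation, csf_name)
    primary = build_primary_sensory_rois(parcellation)

    rois = {
        "MGN_left": froi.mgn_left,
        "MGN_right": froi.mgn_right,
        "LGN_left": froi.lgn_left,
        "LGN_right": froi.lgn_right,
        "AC_left": primary["AC_left"],
        "AC_right": primary["AC_right"],
        "VC_left": primary["VC_left"],
        "VC_right": primary["VC_right"],
    }
    for name, mask in rois.items():
        if mask.size == 0:
            return {
                "participant_kept": False,
                "exclusion_reason": f"empty ROI {name}",
            }

    keep_masks = []
    for run in runs:
        tr = run.series.tr_seconds
        n = run.series.n_volumes
        keep = np.ones(n, dtype=bool)
        if run.censor is not None:
            keep &= np.asarray(run.censor, dtype=bool)
        if run.eye_closures is not None and len(run.eye_closures):
            keep &= rsfc_mod.eye_closure_censor(
                run.eye_closures, tr, n, cfg.eye_closure_min, cfg.eye_gap_merge
            )
        keep_masks.append(keep)
    pruned, run_keep, participant_keep, retention = rsfc_mod.apply_retention_rules(
        keep_masks, runs[0].series.tr_seconds, cfg
    )
    report: dict = {"retention": retention, "participant_kept": participant_keep}
    if not participant_keep:
        report["exclusion_reason"] = "retention rules"
        return report

    per_run_roi: list[dict[str, np.ndarray]] = []
    nuisances: list[np.ndarray] = []
    for run, keep, ok in zip(runs, pruned, run_keep):
        if not ok:
            continue
        tr = run.series.tr_seconds
        norm = rsfc_mod.mode1000_normalize(run.series, brain)
        norm = rsfc_mod.detrend_center(norm)
        series_stack = np.stack(
            [_roi_series(norm.data, m) for m in rois.values()]
            + [_roi_series(norm.data, wm_mask), _roi_series(norm.data, csf_mask)]
        )
        filtered, kept_idx = rsfc_mod.bandpass_with_interpolation(
            series_stack, keep, tr
        )
        roi_ts = {name: filtered[i] for i, name in enumerate(rois)}
        wm_ts_full = series_stack[-2]
        csf_ts_full = series_stack[-1]
        nuis_full = rsfc_mod.build_rsfc_nuisance(
            np.asarray(run.motion, dtype=float), wm_ts_full, csf_ts_full, tr
        )
        per_run_roi.append(roi_ts)
        nuisances.append(nuis_full[kept_idx])

    estimates = {}
    for seed, target in (
        ("MGN", "AC"),
        ("MGN", "VC"),
        ("LGN", "AC"),
        ("LGN", "VC"),
    ):
        est = rsfc_mod.roi_pair_connectivity(
            [(r[f"{seed}_left"], r[f"{seed}_right"]) for r in per_run_roi],
            [(r[f"{target}_left"], r[f"{target}_right"]) for r in per_run_roi],
            nuisances,
            pair=f"{seed}-{target}",
        )
        estimates[f"{seed}-{target}"] = est
    report["estimates"] = {k: v.participant_value for k, v in estimates.items()}
    report["run_estimates"] = {k: v.run_values for k, v in estimates.items()}
    return report
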