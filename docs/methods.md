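# Methods notes

This note records the model assumptions, parameter choices, numerical
details, and known limitations of the implementation. It documents design
reasoning only; every empirical number quoted here is computed by the test
suite or `scripts/acceptance.py`.

## Task model and timing

The localizer uses clustered-sparse temporal acquisition: no volumes are
collected during stimulation; 3 volumes are acquired at the end of every 12 s
trial. Trial decomposition is exact by construction:
`cluster = volumes_per_cluster × TR`, `gap = (12 − 9 − cluster) / 2`, which
reproduces the two site protocols (gap 225 ms / cluster 2.55 s at TR 850 ms;
300 ms / 2.40 s at TR 800 ms). A run is 1 fixation + 16 stimulus trials; the
fixation trial also ends in an acquisition cluster, giving 51 volumes per
run. "Pseudorandom" condition order is implemented as an unconstrained seeded
permutation of 8 auditory + 8 visual trials; `max_condition_run` optionally
rejects long same-condition streaks, since no constraint is inherent to the
design. Run lead-in time is exposed as a parameter but defaults to zero; the
schedule carries explicit per-volume acquisition times so nothing downstream
assumes contiguous sampling.

Condition regressors are 0/1 indicators over acquired volumes, *not*
convolved with an HRF: with 9 s stimulation the response is at or near its
plateau when the cluster is acquired, and sparse sampling precludes a
continuous HRF model anyway. Two indicator columns for the second and third
volume of each cluster absorb the T1-relaxation (non-steady-state) decay;
a regression test verifies that omitting them biases condition betas on
decaying data while including them restores exact noiseless recovery.

## Phantom

The phantom is the package's test bed; its defaults define the conditions
under which recovery is demonstrated.

*Anatomy* — deterministic ellipsoids on a RAS+ 2 mm grid (default 48³),
scaled linearly for other shapes (minimum 32³). Spatial relations follow the
real geometry the search-region rules depend on: LGN lateral and superior to
MGN, pulvinar superior/posterior to both, mediodorsal nucleus
anterior-superior, cortex regions (AC/VC surrogates) embedded in a cortical
shell. Geniculi default to ~40–60 voxels, the plausible range at 2 mm.
Earlier structures win ties, so labels are disjoint by construction.

*Task runs* — each acquired volume is
`baseline × decay(position in cluster) + condition amplitude + N(0, σ)` in
responsive structures (MGN/AC auditory; LGN/VC visual). Defaults: baseline
1000, amplitude 20 (a 2% response), σ = 10, decay (1, 0.97, 0.95). The decay
factors are arbitrary but non-unity so the volume-2/3 regressors are
genuinely exercised. There is no HRF dynamics, spatial autocorrelation of
noise, susceptibility dropout, or motion-correlated signal — so passing
recovery tests demonstrates the pipeline's logic and numerics, not robustness
to those real-data effects.

*Rest runs* — four unit-variance band-limited latents (Fourier synthesis
restricted to 0.009–0.08 Hz) are mixed by the Cholesky factor of the target
correlation matrix (MGN↔AC, LGN↔VC, weak cross-modal floor). The
innovations are orthonormalized before mixing, so the *sample* correlation of
the latents equals the target exactly; recovery error then reflects only the
analysis chain (ROI averaging, nuisance signals, noise, filtering). Both
hemispheres carry the same latent. Cortical latents extend
`cortex_margin_voxels` (default 2) beyond the anatomical parcel: the
connectivity field of a cortical region does not stop at its label boundary,
and this is precisely what makes dilated a-priori ROIs informative. WM, CSF,
and global nuisance series (defaults 0.5, 0.5, 0.1 in latent-SD units) plus
white voxel noise (0.5) complete the model. The global component is
deliberately *not* in the RSFC nuisance set (the method uses no global-signal
regression), so a strong planted global floor inflates cross-modal estimates
— visible in the phantom as MGN–VC ≈ 0.1 rather than the planted 0.05.

## Localization details

- Dilation and erosion use the full 3×3×3 (26-connectivity) element; cluster
  contiguity is 18-connectivity (faces + edges), the dominant fMRI
  convention, exposed as a config option.
- Compartment (WM/CSF) nuisance masks are eroded up to 3 times, skipping any
  erosion that would leave fewer than 2 voxels.
- "Top 10% of contrast values" is a count — `ceil(0.10 × N)` in-mask voxels —
  with ties broken by value then linear voxel index, so selections are
  deterministic. VC uses the lower tail of Auditory−Visual.
- Hemispheric AC/VC series are averaged unweighted across hemispheres.
- TSR rule order: subtract surrounding structures (cortical GM,
  parahippocampal WM, hippocampus undilated; mediodorsal, insular WM, choroid
  plexus, pulvinar, putamen, pallidum dilated by 1), trim the two
  posterior-most occupied slices, then (MGN only) remove voxels superior to
  the inferior-most undilated pulvinar slice. Each rule logs its removals and
  the budget closes exactly. Anatomical directions come from the affine, not
  array axis order.
- "WM within 1–5 voxels of the TSR in any direction" is Chebyshev distance:
  `dilate(tsr, 5) \ tsr ∩ WM`.
- The adaptive threshold keeps fraction `numerator / mean hemispheric TSR
  size` (capped at 1) per hemisphere, i.e. ≈ 32 (MGN) or ≈ 20 (LGN) voxels.
  The numerators are deliberate roughly-sized-fROI constants, not anatomical
  truths; both are configuration parameters, and real-data fROIs need not
  match them in size.
- Coactivation maps for AC and VC do not partial each other out; specificity
  comes from removing voxels surviving in both thresholded maps.
- Multi-run GLM is a single block-diagonal fit with per-run columns
  (per-run fits then averaging is equivalent for the contrast). WM/CSF task
  nuisance columns are mean-centered per run. Motion enters the task GLM
  unfiltered; only the RSFC nuisance filters it.
- QC is automated (empty fROI, LGN inferior/medial to MGN, left/right size
  ratio > 3 by default, MGN/LGN overlap) as a surrogate for consensus visual
  review; the asymmetry bound is a package default, not an empirical value.

## RSFC details

- Mode-1000 normalization estimates the mode as the center of the fullest of
  100 histogram bins over all in-brain values.
- Censoring thresholds Φ_F = 0.07587 mm (low-pass-filtered framewise
  displacement) and d_G = 3.105 (GEV-DV) are consumed as parameters; the
  optimization that produced them, and the computation of the metrics
  themselves, are out of scope — the module accepts precomputed metrics or
  keep-masks.
- Eye-closure censoring removes volumes overlapping closures strictly longer
  than 3 s, and everything between two such closures less than 30 s apart.
  A volume occupies `[t·TR, (t+1)·TR)` and any overlap censors it.
- Retention: kept segments < 8 s censored; runs < 90 s dropped; participants
  with < 2 runs or < 300 s total excluded (with the reason reported).
- Filtering: censored points are linearly interpolated (edges held at the
  nearest retained value), a second-order zero-phase Butterworth band-pass
  (0.009–0.08 Hz, `filtfilt`) applied, `ceil(22 s / TR)` volumes discarded
  per end (26 at TR 0.85 s, 28 at 0.80 s), then censored volumes dropped.
  Correlations use retained volumes only.
- The 28-column nuisance set: band-passed motion parameters, their squares,
  their backward-difference derivatives (first element 0), squares of those
  derivatives, WM and CSF with their derivatives. Squaring follows filtering
  and differentiation. WM/CSF are unfiltered by default (config switch), as
  the filtering rule is stated only for the motion parameters.
- Partial correlation residualizes both series on the nuisance matrix plus
  intercept via least squares and correlates the residuals; degenerate
  (constant-residual) series yield r = 0 and are flagged. Tests verify
  agreement with an independent inverse-covariance (precision-matrix) oracle
  to < 1e-10.
- FDR is Benjamini–Hochberg step-up. Degenerate paired samples (zero-variance
  differences) return t = 0, p = 0.5 rather than NaN.

## Problem sizes used in validation

Recovery checks run on the 48³ phantom with 4 task runs (204 volumes) at the
default SNR, where all four fROIs reach Dice ≥ 0.6 against the planted
nuclei. Resting recovery uses a 32³ phantom at 10,000 volumes with reduced
noise/nuisance amplitudes (σ = 0.1, WM/CSF 0.2, global 0.05), recovering
planted r = 0.5 within ±0.05. Null calibration simulates 500 cohorts of 20
participants at 120 volumes each from ROI-level series; the uncorrected
rejection rate of the selectivity t-tests stays within two standard errors
of 5%.

## Known limitations

- No HRF modeling, prewhitening, or AR noise; the GLM is plain OLS per voxel.
- The nearest-neighbour label resampler replaces dedicated resampling tools;
  nonlinear warps and surface formats are out of scope (inputs are assumed
  already on the BOLD grid).
- ComBat site harmonization, permutation inference on seed maps, and the
  group-level rank tests are not implemented.
- The phantom's MGN rule interaction is benign by construction; on real
  segmentations the "superior to the inferior-most pulvinar slice" rule can
  remove most of a hemisphere's MGN-TSR — construction fails loudly with a
  per-rule removal log if a TSR empties.
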