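# phasequant

Quantitative image analysis for biomolecular condensates, built around the
measurements used to characterize telomeres as shelterin/DNA liquid
condensates: droplet segmentation and settled-volume phase diagrams,
saturation-concentration (c_sat) estimation, droplet fusion kinetics,
anomalous diffusion and first-passage analysis of nuclear loci, FRAP
normalization, coalescence intensity bookkeeping, dilute-phase scaling model
comparison, and 3D DNA-damage foci counting.

It is written for quantitative cell biologists and biophysicists who have
multi-channel fluorescence microscopy data (TIFF + metadata), particle
trajectories, or FRAP traces, and want the full analysis chain as tested,
scriptable Python rather than a sequence of Fiji/MATLAB steps. Because such
studies rarely deposit raw images, every input the pipeline consumes can be
generated synthetically with known ground truth (`phasequant.synthetic`),
so each estimator is validated by parameter recovery.

## The quantities at the core

- **Saturation concentration.** Settled condensate volume per coverslip area
  V(c) grows linearly with total protein concentration above the phase
  boundary; ordinary least squares on the conditions with measurable volume
  gives c_sat as the x-intercept, with its standard error from the delta
  method. Droplets are segmented with the Phansalkar local-adaptive
  threshold, T = μ·(1 + p·e^{−qμ} + k·(σ/r − 1)) over a 30 px window, with
  a 10 px minimum size; single-droplet volume comes from the projected
  ellipse via c = √(a·b), V = (4/3)π·a·b·c.
- **Fusion time.** The time from the last frame where two droplets are
  separate to the first frame where the fused droplet is spherical
  (aspect ratio ≤ 1.1, held 2 frames). Gel-like pairs that never relax are
  right-censored, never assigned a time.
- **Subdiffusion.** Telomere trajectories (LoG detection, optimal
  frame-to-frame assignment, no gap closing) yield the ensemble
  time-averaged MSD; fitting MSD(τ) = D·τ^α + 4σ_loc² recovers the
  anomalous exponent α and generalized coefficient D (μm² s^−α) free of the
  static localization-error floor. First-passage times for two loci at
  separation d follow t = (d²/2D)^{1/α}.
- **FRAP.** Double normalization (bleach ROI over pre-bleach mean, times the
  reference's pre-bleach mean over its current value) cancels acquisition
  photobleaching; full-scale rescaling pins the pre-bleach mean to 1 and the
  first post-bleach point to 0, so the plateau reads off the mobile fraction.
- **Dilute-phase scaling.** c_dil vs c_tot discriminates single-component
  (buffered: c_dil pins at a ceiling) from heterotypically stabilized
  (strictly increasing, sublinear) condensation by AICc model comparison.
- **Foci counting.** Otsu nuclei, 3D LoG puncta, centroid-based assignment
  to nuclei, ≥1-voxel colocalization, and the damage classifier: the
  fraction of nuclei with more than 10 damage foci.

## Worked example

```python
import numpy as np
from phasequant import synthetic as syn, motion as mo, phase as ph

# trajectories generated at the fitted law MSD = 2.8e-3 · τ^0.54, 20 nm noise
trajs, _ = syn.make_fbm_trajectories(alpha=0.54, D_gen=2.8e-3, n_traj=200,
                                     n_frames=300, loc_noise=0.02, seed=0)
fit = mo.msd_powerlaw_fit(mo.compute_msd(trajs), fit_range=(2.0, 30.0))
print(f"alpha = {fit.alpha:.3f}, D = {fit.D:.2e}")
days = mo.encounter_time(fit, 6.8) / mo.SECONDS_PER_DAY
print(f"encounter across 6.8 um: ~{days:.0f} days")
print(f"1000 copies in a 100 nm punctum: {ph.local_concentration(1000, 0.1):.0f} uM")
```

prints (seed 0):

```
alpha = 0.551, D = 2.62e-03
encounter across 6.8 um: ~167 days
1000 copies in a 100 nm punctum: 396 uM
```

i.e. the exponent and coefficient are recovered within sampling error of the
generative values, the extrapolated encounter time across the mean
inter-telomere distance is of order 200 days (which is why telomeres
essentially never meet by diffusion), and a 1,000-copy telomere of 100 nm
radius holds its protein at ~400 μM — orders of magnitude above the
saturation concentration measured in vitro.

The `analysis/` directory holds numbered drivers that run each stage of the
study on synthetic data and write tables under `results/`:
`01_droplet_phase.py` (c_sat 1.8/19 μM recovery, reentrance),
`02_fusion_kinetics.py` (21 s / 27 s fusion, gel censoring),
`03_telomere_motion.py` (α, D, encounter times, local concentration),
`04_frap_recovery.py` (mobile fractions), `05_nuclear_foci.py` (foci counts,
coalescence conservation, dilute-phase model selection).

A `phasequant` CLI wraps the same library functions
(`phasequant simulate|droplets|phase|fuse|track|msd|frap|foci|coalesce|dilute`).

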