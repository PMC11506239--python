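# fpetbold

Analysis pipeline for **simultaneous [¹⁸F]FDG functional PET (fPET) and
BOLD-fMRI** under an optogenetic block-stimulation design, exercised
end-to-end on a seeded synthetic phantom cohort.

## The problem

Under a bolus + constant-infusion FDG protocol, tracer accumulates
irreversibly, so a voxel's time–activity curve (TAC) is near-linear; a
task that raises glucose metabolism adds extra uptake *slope* while the
stimulation is on. Simultaneously acquired BOLD-fMRI gives the
hemodynamic counterpart of the same events. This package implements the
statistical machinery to detect and compare both responses:

- **fPET GLM.** Each voxel's TAC is modelled as
  `y = β₁·r(t) + β₂·b(t) + β₀ + ε`, where `r(t)` is a **ramp regressor**
  (unit slope per frame while stimulation is active, flat during rests —
  the integral of the task boxcar) and `b(t)` is the empirical baseline:
  the mean course of gray-matter voxels *excluding* those declared
  activated, which captures the shared uptake curve without task
  contamination. `β₁` is the task-attributable uptake slope.
- **BOLD GLM.** Block regressors convolved with a canonical double-gamma
  HRF (5-s peak, late undershoot); the inter-block baseline is the
  implicit contrast reference.
- **Group inference.** Voxel threshold P < 0.001, clusters formed with
  26-connectivity, and cluster-level family-wise error controlled by the
  permutation distribution of the maximum cluster size (sign flips for
  one-sample, group-label shuffles for two-sample designs).
- **Group spatial ICA with kurtosis sorting.** Whole-brain-normalized
  fPET series are PCA-reduced (>99% variance), temporally concatenated,
  whitened and unmixed with FastICA (20 components). Components are
  ranked by **spatial excess kurtosis** — task components are spatially
  sparse — so the stimulation component is identified without any timing
  information. Four descriptors are reported per component: kurtosis,
  skewness, spatial variability and spectral-centre frequency.
- **MVPA.** Leave-one-subject-out decoding of stimulation vs baseline
  from per-block patterns (ROI and searchlight), with permutation
  significance (`p = (1 + #{null ≥ observed}) / (1 + n_perm)`), the
  searchlight thresholded at 65% accuracy with cluster correction.
- **Connectivity.** Seed-based correlation (Fisher z) computed
  separately on stimulation and rest windows, contrasted as a paired
  permutation test — "molecular connectivity" for fPET residuals,
  functional connectivity for BOLD.
- **Overlap.** Cross-modal comparison of thresholded maps by the Dice
  percent-overlap ω = 2·V_km / (V_k + V_m) plus peak-coordinate
  distances.

Because no imaging data are deposited for this design, the package ships
a first-class **phantom generator** (`fpetbold.phantom`): linear FDG
uptake with stimulation-dependent slope increments, BOLD block responses
with suppressed on-plateau, post-block overshoot and contralateral
negative responses, slow drift and Gaussian noise, for two groups
(stimulation-responsive "ChR2" and non-responsive "GFP" controls), all
seeded and accompanied by a ground-truth table.

## Worked example

```python
import numpy as np
from fpetbold import (PhantomSpec, simulate_cohort, StimulationProtocol,
                      FrameTiming, pulse_duration, cycles_per_block,
                      block_frame_indices, fit_glm, cluster_inference)
from fpetbold.glm import fpet_baseline_regressor, fpet_design, region_summary

protocol = StimulationProtocol()          # the study's block design
timing = FrameTiming.uniform(95, 60.0)    # 95 one-minute PET frames
print("pulse duration:", pulse_duration(protocol), "s")
print("on/off cycles per block:", cycles_per_block(protocol))
print("last-block frames:", block_frame_indices(protocol, timing, 6))

spec = PhantomSpec(n_chr2=10, n_gfp=10, seed=42)
cohort = simulate_cohort(spec, include_bold=False)
atlas = cohort.atlas
task = np.zeros(atlas.label_volume.shape, bool)
for name in spec.fdg_task_slope_increment:
    task |= atlas.mask(name)

beta_maps = []
for subject in cohort.group("chr2"):
    baseline = fpet_baseline_regressor(subject.fpet, atlas.gray_matter_mask(), task)
    design = fpet_design(spec.protocol, subject.fpet.timing, baseline)
    result = fit_glm(subject.fpet, design)      # VoxelGLM(...).fit()
    beta_maps.append(result.beta_map("ramp"))

table = cluster_inference(np.stack(beta_maps), cohort.subjects[0].fpet.brain_mask,
                          voxel_p=0.001, alpha=0.05, n_perm=200, seed=42,
                          voxel_size=spec.voxel_size)
print(table.clusters[["size_voxels", "peak_t", "p_corrected"]].head(3))
summary = region_summary(table.t_map, table.significant_mask(), atlas)
print(summary[summary.pct_significant > 0][["region", "pct_significant", "mean_t"]])
```

prints

```
pulse duration: 0.025 s
on/off cycles per block: 8
last-block frames: (86, 95)
   size_voxels     peak_t  p_corrected
0          216  35.393149     0.004975
1          180  57.579857     0.004975
2          180  65.696760     0.004975
           region  pct_significant     mean_t
0  right_striatum            100.0  18.159850
2        right_sn            100.0  27.183533
3  right_thalamus            100.0  13.908057
```

The 20-Hz, 50%-duty pulse train gives 25-ms pulses; each 10-min block
holds eight 60-s-on/15-s-off cycles; with a 20-min pre-stimulation
baseline the sixth block covers frames 86–95. On the phantom, the ramp
GLM plus permutation cluster inference recovers exactly the three
regions carrying injected uptake-slope increments (corrected
P ≈ 0.005, the smallest value attainable with 200 permutations).

A configuration-driven run of all arms is available from the shell:

```bash
fpetbold report --config config.yaml --out results_dir
```

with subcommands `simulate`, `preprocess`, `glm-fmri`, `glm-fpet`,
`ica-fpet`, `mvpa`, `connectivity`, `overlap`, `report`.

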