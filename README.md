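# mbfmri

Group-level evaluation of multiband (simultaneous-multislice) fMRI
acquisition sequences, exercised end-to-end on a synthetic BOLD cohort
generator — no data download required.

## The problem

Multiband excitation acquires several slices per readout, cutting the volume
repetition time TR by the MB factor. Faster sampling buys more volumes per
session but costs signal: the flip angle must track the Ernst angle
`θ_E = arccos(exp(−TR/T1))`, steady-state signal falls as
`√((1−E)/(1+E))` with `E = exp(−TR/T1)`, grey–white contrast shrinks, and
parallel-imaging reconstruction inflates noise by the spatially varying
g-factor (≥ 1). Whether MB helps *group-level* statistics for cognitive
block-design tasks — small effects, real between-subject variability — is an
empirical question. This package implements the full comparison machinery a
study of that question needs, for anyone designing or evaluating accelerated
acquisition protocols:

- **`sequences`** — acquisition schemes (five bundled: TRs
  2.45/2.00/1.22/0.70/0.63 s) and the Ernst-angle / steady-state physics.
- **`simulate`** — a multi-subject, multi-sequence cohort generator:
  26 seven-second blocks (13 CA + 13 CC), 8–12 s intervals, ~8 min runs;
  tissue baselines that saturate with TR, AR-coloured thermal noise scaled
  by g-factor and voxel volume, aliased physiological sinusoids, drifts,
  motion tables with jerk artefacts, 20 planted resting-state networks, and
  per-subject activation amplitudes drawn around a population mean.
- **`firstlevel`** — subject GLM: canonical double-gamma HRF (optional
  temporal/dispersion derivatives), 6 motion + 5 CSF + 5 WM CompCor
  nuisance regressors, 128 s discrete-cosine high-pass, pooled
  autocorrelation whitening (`exp-basis`, `ar1` or `none`), contrasts,
  task residualization for pseudo-rest, 6 mm Gaussian smoothing.
- **`grouplevel`** — random-effects one-sample t maps, Benjamini–Hochberg
  FDR at q = 0.05 with a 50-voxel cluster filter, t histograms, map
  correlation, residual smoothness (FWHM) estimation, run truncation.
- **`varcomp`** — the variance decomposition
  `σ²(v) = (1/N)·(c X⁽¹⁾⁻ X⁽¹⁾⁻ᵀ cᵀ)·C⁽¹⁾(v)` from the pooled fixed-effects
  model, with `Σ² = ResMS_RFX − σ²` by subtraction, plus 6 mm ROI-sphere
  summaries.
- **`concordance`** — ROC/hit/false-alarm comparison of thresholded group
  maps and atlas-region activation tables with the 5 % activity rule.
- **`pseudorest`** — two-stage dual regression of task-residualized runs
  against 20 network templates; per-network group maps, supra-threshold
  counts and normalized cumulative histograms `N(t ≥ x)/N_ref`.
- **`metrics`** — raw/effective/per-unit-time tSNR, grey–white CNR, and the
  noncentral-t power calculator for minimal detectable effect sizes.
- **`cli` / `pipeline`** — `mbfmri` command with `simulate`, `first-level`,
  `group`, `varcomp`, `concordance`, `pseudorest`, `metrics`, `power`,
  `report` and `run-all` subcommands over a YAML config.

## Worked example

Simulate eight subjects under the slowest and fastest bundled schemes and
compare their thresholded group maps:

```python
import numpy as np
from mbfmri import (NoiseModel, default_sequence_table, generate_phantom,
                    generate_task_design, simulate_subject)
from mbfmri.firstlevel import (Contrast, build_design, compcor_regressors,
                               contrast_tmap, fit_glm, gaussian_smooth)
from mbfmri.grouplevel import rfx_ttest, threshold_group

specs = {s.name: s for s in default_sequence_table()}
phantom = generate_phantom(grid_shape=(20, 22, 20), seed=0)
noise = NoiseModel()                       # between-subject SD 0.3 % signal
rng = np.random.default_rng(0)
effects = 1.2 + noise.between_subject_sd * rng.standard_normal(8)

for name in ("MB1S22.7iso2.45", "MB4S22.7iso0.63"):
    spec, maps = specs[name], []
    for s in range(8):
        design = generate_task_design(seed=10 * s)
        series, motion = simulate_subject(phantom, design, spec, noise,
                                          subject_effect=effects[s],
                                          seed=100 + s)
        cc = np.column_stack(
            [compcor_regressors(series, phantom.csf_mask, k=5),
             compcor_regressors(series, phantom.wm_mask, k=5)])
        X = build_design(design, spec, motion=motion, compcor=cc)
        fit = fit_glm(gaussian_smooth(series, 6.0), X,
                      pool_mask=phantom.gm_mask)
        _, con = contrast_tmap(fit, Contrast.from_names(X, "task_CA",
                                                        "task_CC"))
        maps.append(con)
    g = threshold_group(rfx_ttest(np.stack(maps), phantom.brain_mask),
                        q=0.05, k=20)
    print(f"{name}: {int(g.sig_mask.sum())} significant voxels, "
          f"t cutoff {g.t_at_q:.2f}, peak t {g.tmap.values.max():.1f}")
```

prints

```
MB1S22.7iso2.45: 648 significant voxels, t cutoff 3.40, peak t 33.8
MB4S22.7iso0.63: 688 significant voxels, t cutoff 3.36, peak t 25.1
```

Both schemes recover the planted activation (q_FDR < 0.05, cluster ≥ 20 on
this small grid); the faster scheme finds slightly more voxels at a slightly
lower t cutoff — more samples outweighing its g-factor penalty. The power
calculator is also available from the shell:

```sh
$ mbfmri power --n 3 --n 14 --n 23
   n  detectable d
   3         2.297
  14         0.702
  23         0.535
```

i.e. three subjects only detect enormous effects (d ≈ 2.3); 23 subjects
reach d ≈ 0.5 at one-tailed α = 0.05 and 80 % power.

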