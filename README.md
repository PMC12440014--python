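# laminalpha

Laminar EEG-fMRI analysis of alpha–BOLD coupling: where, across cortical
depth, does spontaneous 8–13 Hz alpha power couple to the BOLD signal?

Gradient-echo BOLD at sub-millimetre resolution is biased toward the pial
surface: ascending venules drain deoxyhemoglobin-driven signal from deep
layers into superficial ones, so a raw depth profile mostly reflects venous
architecture rather than neural laminae. `laminalpha` implements a complete,
tested pipeline for this problem, aimed at researchers analysing laminar
EEG-fMRI experiments and at methodologists who want each stage testable in
isolation:

- **alpha regressors** — Hilbert envelope of the 8–13 Hz band, TR/4 segment
  repair, double-gamma HRF convolution, per-volume sampling; boxcar and
  alpha-orthogonalised variants,
- **voxelwise GLM** — OLS with six motion nuisance regressors, exact t→z
  quantile mapping, negative-tail cluster correction (z < −2.3, p < 0.05)
  by a sign-flipping permutation null, fixed effects over runs,
  nearest-neighbour upsampling,
- **equivolume depths and columns** — six depth bins holding equal tissue
  volume under local curvature, columns grown geodesically from mid-depth
  seeds, the any-depth column-inclusion rule and the 5% |β| threshold,
- **deveining** — spatial deconvolution of the draining-vein accumulation,
  with per-column weights v_i = λ·ALFF_i/mean(ALFF) (λ = 0.25 by default):

  ```
  measured:  m_1 = b_1,   m_i = b_i + v_i · Σ_{j<i} b_j     (i = 2..6)
  deveined:  b̂_1 = m_1,   b̂_i = m_i − v_i · Σ_{j<i} b̂_j
  ```

- **vein diagnostics** — unsharp-mask vein detection on the mean EPI, a
  four-fold-dilation surrounding-vein ring, 25/50/25 classification of
  columns by deveining-induced gradient change, ring-overlap statistics and
  exclusion of the most-affected quarter,
- **depth-profile statistics** — global-mean and column-profile-mean
  profiles over negative β voxels, range normalisation, column-count-
  weighted ROI averaging, one- and two-way repeated-measures ANOVA with
  Bonferroni post-hocs,
- **synthetic subjects** — a curved GM ribbon with penetrating veins,
  block-modulated alpha timecourses, draining-vein physics and venous
  low-frequency fluctuations, with full ground truth for recovery tests.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate eight subjects whose middle cortical depths respond at half
amplitude (an "n"-shaped laminar truth), run the full analysis, and test
the group depth effect:

```python
import numpy as np
from laminalpha import PipelineConfig, rm_anova_1way
from laminalpha.pipeline import make_geometry, simulate_subject, analyze_subject, group_matrix
from laminalpha.synthdata import GroundTruthProfile
from laminalpha.core import spawn_seeds

cfg = PipelineConfig(n_veins=0, perivascular_gain=0.0)
geometry = make_geometry(cfg)
analyses = []
for s in spawn_seeds(cfg.seed, 8, tag="subjects"):
    sim = simulate_subject(cfg, s, geometry=geometry, truth=GroundTruthProfile.n_shape())
    analyses.append(analyze_subject(sim, kinds=("alpha",), seed=s))

unc = np.stack([a.kinds["alpha"].profile_uncorrected.mean for a in analyses]).mean(0)
mat = group_matrix(analyses, kind="alpha", corrected=True)
eff = rm_anova_1way(mat)
print("uncorrected group profile (beta):", np.round(unc, 2))
print("deveined group profile (normalised):", np.round(mat.mean(0), 2))
print(f"depth effect: F({eff.df1},{eff.df2}) = {eff.F:.1f}, p = {eff.p:.2e}")
```

Output:

```
uncorrected group profile (beta): [-4.   -4.24 -4.63 -5.35 -8.22 -9.88]
deveined group profile (normalised): [-1.99 -1.99 -1.   -0.99 -1.99 -1.99]
depth effect: F(5,35) = 705525.1, p = 1.68e-86
```

Reading it: the uncorrected profile grows monotonically in magnitude toward
depth 6 (the pial surface) — the draining-vein bias, not neuroscience. After
deveining, the profile recovers the implanted "n" shape: the weakest
(least negative) alpha–BOLD coupling sits at middle depths 3–4, and the
repeated-measures ANOVA across depths confirms the depth effect. Depth 1 is
WM-adjacent, depth 6 CSF-adjacent; β values are negative because alpha power
and BOLD anticorrelate.

The same chain is available from the shell:

```sh
laminalpha all --out out/ --seed 1 --n-subjects 2
laminalpha simulate --out sim/ --seed 3 --n-subjects 1
laminalpha layers --labels sim/labels.nii --n-columns 16 --out layers/
```

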