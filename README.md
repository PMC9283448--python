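# hippodti

Gray-matter DTI at high b-value: how diffusion weighting and the number of
encoding directions shape what the tensor model can see in the mouse
hippocampus.

## The problem

Diffusion tensor imaging (DTI) models the dMRI signal in each voxel as a
Gaussian ellipsoid and summarises it with fractional anisotropy (FA), mean,
axial and radial diffusivity (MD, AD, RD).  In gray matter the interesting
microstructure — densely packed dendrites in the hippocampal layers — only
becomes visible with strong diffusion weighting (b ≈ 2700 s·mm⁻² rather
than the standard 1000) and enough encoding directions (NDIR), but strong
weighting costs SNR and pushes the signal outside the Gaussian regime.
`hippodti` is a tested re-implementation of the evaluation pipeline for this
trade-off, exercised on a synthetic "digital hippocampus" cohort:

* **Direction schemes** (`hippodti.schemes`) — electrostatic-repulsion shell
  generation (single- and joint two-shell), the antipodally symmetric angle
  metric d(u,v) = arccos|u·v|, and the greedy subsampling rule: repeatedly
  remove the vector with the most neighbours at d < 30°, recomputing counts
  after each removal, to derive reduced datasets (43→22→12 directions) from
  an acquired shell.
* **Digital phantom** (`hippodti.phantom`) — three adjacent hippocampal
  layers (SR, SLM, ML), a corpus-callosum band and air background; per-layer
  axially symmetric signal S = S0·exp(−b̃D(g) + b̃²D(g)²K(g)/6) with
  b̃ = b/1000, calibrated from published two-shell apparent diffusivities;
  Rician noise at a configurable b=0 SNR; between-animal variability; an
  EAE (dendritic-loss) effect in ML that only the high-b shell can see.
* **Models** (`hippodti.models`) — statsmodels-style `DiffusionTensorModel`
  and `DiffusionKurtosisModel` whose `fit()` returns results objects with
  parameter maps, FA/MD/AD/RD (and K_ax, K_rad, K_mean, MKT, KFA for DKI),
  the ln-space fit residue (SSE) and QC counters.  DKI is the constrained
  weighted linear fit with 0 ≤ directional apparent kurtosis ≤ 3.
* **Quality control** (`hippodti.qc`) — background-ROI SNR
  (SNR_global = mean over DW volumes of tissue mean / noise sigma, with the
  Rayleigh correction for magnitude background noise), angular CNR, SSE
  summaries.
* **Statistics** (`hippodti.analysis`) — per-layer VOI tables, rm-ANOVA /
  Friedman layer discrimination with generalized η² / Kendall's W and
  Benjamini–Hochberg–Yekutieli-adjusted post-hocs, k-medoids (PAM, k=3,
  Euclidean) layer classification scored by the adjusted Rand index, and
  unpaired EAE-vs-control tests.

## Worked example

```python
import numpy as np
from hippodti import (
    CohortSpec, DiffusionTensorModel, generate_multishell_set,
    min_angle_report, simulate_cohort, subsample_directions,
)
from hippodti.analysis import standard_dataset_masks

# jointly optimised two-shell scheme, then greedy reduction of the b=2700 shell
b1000, b2700 = generate_multishell_set(22, 43, seed=1)
for s in (b2700, subsample_directions(b2700, 22), subsample_directions(b2700, 12)):
    r = min_angle_report(s)
    print(f"{s.label:<22} mean minimum angle {r.mean_min_angle:5.1f} deg (sd {r.sd_min_angle:.1f})")

# simulate a 15-animal control cohort and fit DTI on the full b=2700 dataset
spec = CohortSpec(n_control=15, n_eae=0, seed=1)
cohort, truth = simulate_cohort(spec, [b1000, b2700])
masks = standard_dataset_masks(cohort[0].scheme)
ds = cohort[0].subset(masks["B2700-43Dir"], "B2700-43Dir")
result = DiffusionTensorModel.from_dataset(ds).fit()
print(result.summary())
print(result.voi_means(ds.labelmap).round(3)[["layer", "n_voxels", "FA", "MD", "AD", "RD"]])
```

prints

```
B2700-43Dir            mean minimum angle  19.9 deg (sd 0.6)
B2700-43Dir->22Dir     mean minimum angle  24.3 deg (sd 4.9)
B2700-43Dir->12Dir     mean minimum angle  34.7 deg (sd 2.0)

Diffusion tensor fit (log-linear WLS)
  fitted voxels : 3456 / 13824
  floored sigs  : 0
  neg-eig frac  : 0.0000
  metric   mean     sd
  FA       0.2494   0.1688
  MD       0.4301   0.0327
  AD       0.5545   0.0495
  RD       0.3678   0.0717
  SSE      0.0711   0.0206

layer  n_voxels    FA    MD    AD    RD
   SR       864 0.117 0.466 0.529 0.435
  SLM       864 0.118 0.443 0.503 0.413
   ML       864 0.234 0.433 0.552 0.374
   CC       864 0.529 0.378 0.634 0.250
```

The minimum-angle means show the greedy reduction trading directions for
angular spacing (19.9° → 24.3° → 34.7°), and the per-layer table shows the
molecular layer standing out from SR/SLM by its higher FA and lower
MD/RD at b = 2700 — the separation that drives both the unsupervised layer
classification and the lesion detection downstream.

A full pipeline run (simulate → reconstruct the five datasets → fit → QC →
statistics → clustering) is one call:

```bash
hippodti run config.toml       # or: from hippodti import run; run("config.toml")
```

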