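# Methods

## Signal model and units

Every tissue class of the phantom carries an axially symmetric parameter
set (D_ax, D_rad, K_ax, K_rad, e₁) and generates diffusion-weighted signal
by the two-term cumulant expansion

    S(b, g) = S0 · exp(−b̃·D(g) + b̃²·D(g)²·K(g)/6),    b̃ = b/1000,

with D(g) = D_rad + (D_ax − D_rad)(g·e₁)² and the same cos² interpolation
for K(g).  Working in b̃ (ms·μm⁻²) keeps all diffusivities in μm²·ms⁻¹, the
unit used for every printed value in the package.  The single-shell
*apparent* diffusivity along g is then adc(b̃) = D(g) − b̃·D(g)²·K(g)/6,
which decreases with b whenever K > 0 — the central b-dependence the
package studies.  The cos² kurtosis profile is the simplest axially
symmetric choice; it is not an exact fourth-order tensor form, so DKI
recovery tests use a separate exact forward model (`models.dki_signal`)
instead of the cumulant phantom.

## Calibration of the gray-matter layers

Each layer's (D, K) pair per eigen-direction is solved in closed form from
two apparent diffusivities (one per shell):

    D²K = 6(adc_low − adc_high)/(b̃_high − b̃_low)
    D   = adc_low + b̃_low·D²K/6,     K = D²K/D².

The defaults invert published in vivo mouse hippocampus axial/radial
apparent diffusivities at b = 1000 (22 directions) and b = 2700
(43 directions), e.g. ML axial (0.676, 0.542) → D_ax ≈ 0.755, K_ax ≈ 0.83
and ML radial (0.466, 0.383) → D_rad ≈ 0.515, K_rad ≈ 1.105.  The corpus
callosum uses plausible rodent white-matter values (D_ax 1.2, D_rad 0.35,
K_ax 0.8, K_rad 1.8) chosen for high anisotropy and kurtosis — deliberately
not calibrated to any measured table; its role is only to provide the
white-matter SSE reference.

## Cohort design

Defaults mirror a post-QC study population: 15 control and 16 EAE animals,
b=0 hippocampal SNR 79.5, grid 48×48×6 voxels at 0.08×0.08×0.2 mm, two b=0
volumes per shell.  Between-animal variability is multiplicative Gaussian
on all D's and K's with total coefficient of variation 0.05, decomposed
into a shared per-animal scale (0.8·cv, a global physiological component
common to all layers) and independent per-parameter jitter (0.6·cv).  The
split keeps the total spread at cv while holding the FA spread near the
published ±0.02 — fully independent perturbations inflate FA variability
(the axial and radial diffusivities then decorrelate), while a fully shared
factor would leave FA essentially constant.

The EAE (dendritic-loss) effect multiplies the ML apparent axial and radial
diffusivities *at b = 2700 only* by (1 − attenuation), default 3.3%, and
re-solves (D, K) from the shifted two-shell pairs.  Holding the b = 1000
apparent values fixed encodes the finding the pipeline must reproduce — the
lesion is invisible at standard weighting — and scaling both eigen-ADCs by
the same factor leaves apparent FA exactly unchanged, so FA "detections"
occur at the false-positive rate.  The magnitude is a free parameter (no
numeric effect size is published); 3.3% puts the per-cohort MD comparison
at p ≈ 0.05 power ~0.7, matching the borderline significances reported.
Note that a lesion parameterised instead as a *decrease of intrinsic D with
the b=1000 ADC held fixed* is not self-consistent: fixing adc(1) while
lowering D forces D²K down and therefore *raises* adc(2.7).

## Direction schemes

The angle metric is d(u,v) = arccos|u·v| (encoding is antipodally
symmetric; the alternative signed convention is indistinguishable on
near-uniform hemispheric sets).  Subsampling removes, one vector per
iteration, the vector with the most neighbours at d < 30° (strict
inequality), recomputing counts each iteration; ties go to the smallest
nearest-neighbour angle, then the lowest index — deterministic and
coverage-preserving.  After each removal every survivor's nearest-neighbour
angle is non-decreasing (a provable invariant); the *set mean* can dip by
O(10⁻³ deg) at individual steps when the removed vector's own minimum angle
was above average, but rises across the reconstructed sizes 43→22→12.

Shells are generated by electrostatic repulsion: pair energy Σ 1/d² over
each point and its antipode, minimised by L-BFGS on unconstrained
coordinates (energy evaluated on the normalised vectors) followed by a
projected-gradient polish that terminates when the largest per-iteration
displacement falls below 10⁻⁸ rad (measured as chord length — the arccos of
a dot product cannot resolve angles below √ε ≈ 1.5·10⁻⁸).  The two-shell
generator minimises the equal-weight sum of both per-shell energies and the
pooled energy, reflecting protocols designed for per-shell *and* combined
uniformity; at (22, 43) it yields mean minimum angles of ≈ 29° and ≈ 20°,
in close agreement with the published scheme it stands in for.

## Tensor and kurtosis fitting

Both fits are log-linear: OLS on ln S followed by one re-weighting pass
with weights equal to the squared predicted signals (iteration count
configurable; the WLS estimate equals OLS exactly on noise-free data).
Zero/negative signals are floored to the smallest positive float with a QC
counter.  SSE is the per-voxel sum of squared residuals in ln-signal space
— the residual space of log-linear fitting; absolute SSE values are
therefore implementation-defined and only orderings (high vs low b, CC vs
hippocampus) are meaningful.  Negative eigenvalues are kept, not clamped
(clamping would bias MD comparisons); their fraction is reported as QC.

DKI estimates 22 parameters (6 tensor + 15 kurtosis components + ln S0)
from both shells jointly and enforces 0 ≤ K_app(g) ≤ 3 and D_app(g) ≥ 0
along every measured direction plus the three tensor eigen-axes.  The
bounds are quadratic-over-linear in the parameters; voxels violating the
unconstrained solution are re-solved with SLSQP using analytic constraint
Jacobians and mean-normalised weights (without the normalisation the
squared-signal weights, ~10⁵, make the QP numerically unreliable).  Scalar
metrics: K_ax along V1; K_rad as the mean apparent kurtosis over 8 equally
spaced directions in the V2–V3 plane; K_mean over the measured directions;
MKT as the spherical mean of W(g); KFA as the Frobenius-normalised
anisotropy of W about its isotropic part.

## Quality metrics

SNR_global averages, over a dataset's DW volumes, the hippocampal
(SR∪SLM∪ML) mean signal divided by the per-volume noise sigma estimated
from the air background.  Background magnitude noise is Rayleigh, so the
raw background SD is divided by √(2 − π/2) to recover the Gaussian sigma;
with that convention the measured b=0 SNR equals the simulation's target
and the b=1000/b=2700 values follow the mean signal attenuation (≈ 0.57 and
≈ 0.30 of S0 for the calibrated layers).  The angular CNR is the per-voxel
SD of the signal across a shell's DW volumes over the noise sigma — an
explicit, simple definition of direction-generated contrast; it is not
numerically identical to Gaussian-process-based QC tools, so only orderings
are asserted, never absolute values.

## Statistics

Layer discrimination (control animals, SR/SLM/ML): repeated-measures ANOVA
when all per-layer Shapiro–Wilk p ≥ 0.05, with Greenhouse–Geisser
correction when Mauchly's sphericity test fails and generalized η² effect
size (large > 0.140); otherwise Friedman with Kendall's W (large > 0.800).
Post-hoc paired t / Wilcoxon signed-rank p-values are adjusted by the
Benjamini–Yekutieli step-up rule (harmonic-sum correction).  Group
comparison (EAE vs control, per metric and dataset): Shapiro–Wilk per group
selects a t-test (Levene at α = 0.05 choosing homo- vs heteroscedastic) or
the Wilcoxon rank-sum test; p-values are reported unadjusted by design.
The "as appropriate" selection rule (α = 0.05 throughout) is this package's
operationalisation; no specific rule is published.

Unsupervised layer classification uses PAM (k-medoids) with BUILD + SWAP,
k = 3, Euclidean distance on unstandardised (FA, MD, RD) — the three axes
on which the layers are conventionally displayed; AD is excluded by default
as the least discriminating metric, and both the feature list and z-scoring
are exposed as options since the published analysis does not pin them down.
The algorithm is deterministic (greedy BUILD, best-improvement SWAP, ties
to the lowest index).  Agreement with the anatomical truth is the adjusted
Rand index plus a misclassification count after Hungarian cluster-to-layer
matching.

## What the synthetic cohort does and does not show

The phantom reproduces the *mechanisms* under study: kurtosis-driven
b-dependence of apparent diffusivities, SNR loss with b, angular-coverage
loss under subsampling, layer contrast, and a high-b-only lesion.  It omits
EPI artifacts, motion, eddy currents, partial-volume and CSF contamination,
spatially varying orientations within a layer, and the unknown within-animal
covariance of real metrics.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and that the published *patterns* (SNR
chain, metric tables, ARI ordering, detection ordering) follow from the
calibrated signal model — not that the in vivo effect sizes are themselves
re-derived.  Published table values reappear in two roles: apparent
diffusivities are calibration *inputs*, while the SNR chain, the
b=1000/b=2700 MD means, FA, and the clustering/detection orderings are
genuine *outputs* of the simulation and fitting chain.

## Problem sizes

Acquisition-scale checks (SNR chain, cohort-mean metrics, ARIs) use the
full 48×48×6 grid with 15 control animals.  Repeated-cohort orderings
(100 seeds for clustering and lesion detection) use a 24×24×3 grid: VOI
values are spatial means over hundreds of voxels, so cohort-level
statistics are insensitive to the grid size, and the smaller grid keeps a
hundred simulate-fit-test cycles cheap.  The acceptance script uses 30
cohorts for the detection rates (binomial SE ≈ 7 percentage points).

## Known limitations

* The original acquisition's direction vectors are not deposited; the
  electrostatic generator is a stand-in, and user-supplied bvec/bval files
  take precedence when available.
* Constrained DKI falls back to the unconstrained estimate if SLSQP fails
  to converge on a voxel (counted in QC) rather than erroring.
* CNR is definitionally different from eddy-QC tools; never compare its
  absolute values across software.
* The greedy subsampler's tie-break is one reasonable deterministic choice;
  other tie-breaks give direction sets differing by a vector or two, with
  minimum-angle means well inside the published spread.
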