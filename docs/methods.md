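# Methods

## Problem setting

Postoperative recurrence risk in pediatric low-grade glioma is predicted
from a single preoperative T2-weighted volume plus a handful of clinical
covariates (age at diagnosis, extent of resection), with event-free survival
(EFS) as the endpoint. Real cohorts in this disease are small
(a few hundred subjects pooled across institutions), heavily right-censored,
and the imaging cannot be shared. The package therefore couples the modeling
pipeline to a synthetic phantom cohort with fully known hazard structure:
every claim the test suite makes is checked against generator truth or an
independent enumeration oracle.

## Survival model

Discrete-time logistic hazard. Follow-up is partitioned into `J` bins
(default `J = 20`, equidistant over the observed follow-up; a quantile
scheme is available). Each subject's network output is a vector of `J`
logits; the per-bin hazard is the sigmoid of the logit (clamped to
|logit| ≤ 15 so hazards stay strictly inside (0, 1)), and survival is the
running product of `1 − h_j`. The likelihood treats each bin as a binary
regression conditioned on being at risk, so the loss for a subject assigned
to bin `k` (right-closed convention: a time exactly on an interior edge
belongs to the earlier bin; times past the last edge clamp into it) is the
sum of `log(1 − h_j)` over survived bins plus the Bernoulli term in bin `k`.
The gradient with respect to the logits has the closed form `h_j` for
`j < k`, `h_k − d` at `j = k`, and 0 beyond, which the tests verify against
central finite differences.

Three variants share a 3-layer fully connected architecture (hidden width
32 at desk scale, 128 configurable): clinical-only (input: age z-scored with
training-set statistics + 3-level resection one-hot; subjects with missing
resection are dropped by default, with an imputation flag), image-only
(input: the frozen-encoder feature vector, standardized per feature with
training-set statistics), and multimodal (image trunk, clinical vector
concatenated onto the activations entering the final layer). Optimization
is Adam (lr 1e-2, 300 epochs, batch 64), fully seeded.

Regularization differs by input dimensionality. The clinical trunk (4
inputs) uses dropout 0.1 and weight decay 1e-3. The image/multimodal trunk
(128 standardized features against ~100 training subjects at desk scale) is
in the classic small-sample regime for fully connected nets and uses the
canonical heavy-dropout default, p = 0.5, with weight decay 1e-2 and no
early stopping; with lighter regularization the trunk memorizes the
training cohort (training concordance ≈ 0.99) while a ridge probe on the
same features generalizes, which is the diagnostic that fixed this default.
Cross-validated selection of the decay by validation likelihood was
evaluated and found too noisy at this cohort size to improve on the fixed
default.

The scalar risk score is `1 − S(36 months)` (step-constant interpolation,
right-continuous), matching the 3-year horizon used throughout the
evaluation.

## Encoder transfer

A compact 3D U-Net (double 3×3×3 conv + ReLU per level, max-pool 2 between
levels, nearest-upsampling decoder with skip concatenation, 2-class
voxelwise head) is trained on phantom tumor masks with a Dice +
cross-entropy loss. Its deepest encoder activations are
adaptive-average-pooled to a small grid and flattened into a fixed-length
descriptor; the full-size default (5 levels, 32 base channels, growth 2,
pooled 2×2×2) yields 512 × 8 = 4096 features for a [96, 192, 192] input.
Raw flattening of a bottleneck generically does not give a fixed small
length, so the pooling step is the package's reconciliation of "flattened"
with a fixed 4096-long vector. Feature extraction is a pure function of
(weights, volume); survival training never touches the encoder, and a
SHA-256 hash of the encoder weights asserts the freezing contract.

All networks (U-Net, survival MLPs, the from-scratch CNN baseline) are
implemented in numpy with explicit forward/backward passes; 3×3×3
convolution is computed as 27 shifted channel-mixing GEMMs, which bounds
peak memory at a few activation-map copies and runs the arithmetic through
BLAS. Gradient correctness is tested numerically.

## Preprocessing

Bias correction is a log-domain surrogate honoring the N4 contract: the
multiplicative field is estimated by heavy Gaussian smoothing (default
30 mm) of the log-intensity inside the brain mask via normalized
convolution (which extrapolates smoothly outside the mask), divided out,
and rescaled to preserve the within-mask mean exactly. Full B-spline N4 is
intentionally out of scope; external N4 output can be supplied instead.
Resampling is trilinear onto a target spacing (default 1×1×3 mm stored
slice-axis-first as (3, 1, 1)), with the convention `world = origin +
index·spacing`, so a linear ramp resamples exactly and physical extent is
preserved within one voxel. Brain masking is Otsu + largest connected
component + hole fill, or an external mask passed through unchanged.
Intensities are z-scored within the brain mask (background zeroed) and the
volume is center-cropped/zero-padded about the brain centroid to the
network input size. Rigid inter-scan registration is a deliberate no-op:
the pipeline consumes a single sequence per subject.

## Phantom generator

Each subject gets a brain-shaped ellipsoidal foreground and a tumor: a
random-radius ellipsoid (radius 4–10 mm by default) whose surface is
perturbed by a random low-order (l ≤ 2) spherical-harmonic field scaled by
the irregularity knob (0.15 default; 0 gives an exact sphere, which the
volume-oracle test exploits). Intensities are background + contrast·mask
(contrast 1.5), multiplied by a smooth multiplicative field
(`exp(0.2·(mean of 3 random low-frequency cosines))`) and degraded with
Gaussian noise (sd 0.05).

The event process is natively discrete-time so the logistic-hazard model is
correctly specified: each subject has a constant per-bin hazard
`h = σ(β₀ + β_v·log V + β_a·(age−7)/5 + β_r[resection])` with V the tumor
volume in ml, and the event bin is geometric over 20 bins of 6 months
(120-month administrative cap). Defaults: β₀ = −4.4 (site A) / −3.85
(site B), β_v = 0.9, β_a = −0.35, β_r = {GTR −0.6, STR +0.2, biopsy +0.5}.
These were fixed once by simulating the generator against the emulated
two-site structure: observed total event rates 19.7% / 35.8% at n = 4000,
age protective, gross total resection protective, site B younger with fewer
GTRs and more chemotherapy. Ages are triangular per site (modes 8.7 / 5.7
years) — qualitative structure only, no attempt at exact distributional
match.

Censoring: with probability `censor_rate` (default 0.3) a subject draws an
independent uniform censoring time over the follow-up window and is
censored if it precedes the event; subjects event-free at 120 months are
administratively censored. `censor_rate = 1` is a boundary switch meaning
"censor everyone". The interior mechanism is independent random censoring,
which is what the IPCW metrics assume.

What the phantoms do **not** emulate: real MRI physics and artifacts,
anatomical heterogeneity, multifocal or infiltrative growth, scanner/site
appearance shift, time-varying hazards, and informative censoring. One
practical consequence observed in the experiments: the image-to-hazard
signal (tumor volume under high contrast) is learnable end-to-end from
~100 weakly labeled phantoms, so the from-scratch CNN baseline is far more
competitive here than on real MRI; passing tests therefore demonstrate
pipeline correctness and metric validity, not clinical-scale effect sizes.

## Evaluation suite

- **C^td** (Antolini): comparable pairs are (i event, T_i < T_j) or tied
  times with j censored; concordant when `S_i(T_i) < S_j(T_i)`; prediction
  ties count 1/2. With step curves known at the grid edges, `S(T_i)` is the
  survival at the end of the right-closed bin containing `T_i` (evaluating
  at the bin start would turn every first-bin event into an uninformative
  tie on coarse grids). Verified exactly against O(n²) enumeration.
- **Bootstrap**: subject-level resampling, percentile intervals (1000
  draws, 95%), seeded; resamples without comparable pairs are redrawn with
  a hard cap. Intervals are widened, if necessary, to contain the point
  estimate.
- **Time-dependent AUC** (cumulative/dynamic, 36-month horizon): cases are
  events by the horizon weighted `1/G(T−)`, controls subjects at risk
  beyond it weighted `1/G(horizon)`, with `G` the censoring Kaplan–Meier;
  equals the rank-based AUC exactly without censoring.
- **Brier / integrated Brier**: IPCW form; the integration grid is kept
  strictly inside the censoring-KM support. Matches the no-censoring mean
  squared error and a double-loop oracle exactly.
- **Calibration / ECE**: equal-width bins (10) on predicted S(36); bins
  with < 2 subjects merge into their lower neighbor; the observed
  proportion per bin is the within-bin KM survival at the horizon
  (a censoring-naive mode is available behind a flag); ECE is the
  subject-count-weighted mean absolute discrepancy.
- **KM / log-rank**: product-limit and the standard two-group statistic
  with events preceding censorings at ties; verified against hand
  computations and, in the test suite, against lifelines.
- **Stratification**: the risk threshold is the median of the *validation*
  scores — in the pipeline, the pooled out-of-fold predictions of the
  3-fold CV — applied unchanged to the test set (ties to low-risk).
- **Classical tests**: Fisher's exact two-sided p is the
  probability-mass-summation convention (with 1 + 1e-7 relative slack);
  Wilcoxon rank-sum is exact (DP enumeration) for min(n, m) ≤ 10 without
  ties, normal approximation with tie and continuity correction otherwise;
  univariable Cox uses safeguarded Newton on the Breslow partial likelihood
  (Efron available), flags monotone likelihood, and backs the a-priori
  p < 0.15 covariate screen.

## Pipeline

The cohort is split 70/30 into development and test, stratified by (event
status, site), within ±1 subject per stratum; development subjects get
balanced 3-fold assignments. All fitted statistics — clinical normalization,
feature standardization, the time grid, the stratification threshold — are
computed from development data only. Out-of-fold CV predictions supply the
risk-score threshold; the final model is refit on the full development set
(the CV-ensemble alternative was considered and rejected for simplicity)
and evaluated once on the test set. Runs are stamped with a config hash;
stages that already produced their artifact in the run directory are
skipped on rerun. Fine-tuning freezes the encoder and continues training
only the survival head on growing fractions of the external site;
fractions yielding fewer than 5 subjects are skipped. The from-scratch
baseline is a small 3-block CNN (conv–ReLU–pool, global average pool,
linear hazard head) trained end-to-end on the same framed volumes, splits
and grid.

## Problem sizes and numerical choices

Desk-scale defaults, chosen so the full suite and experiments run on a
single CPU: phantom grid 16×32×32 at 3×2×2 mm, U-Net with 3 levels and 4
base channels (feature_dim 128), cohorts of 150–200 subjects, segmentation
training on 30 subjects for 14 epochs. The full-size configuration
(feature_dim 4096 at [96, 192, 192]) is exercised by a single forward pass.
Determinism: every source of randomness flows from explicit integer seeds
through `numpy.random.Generator`; repeated runs are bit-identical, and
results were checked to be independent of BLAS thread count. Degenerate
inputs (empty masks, constant covariates, no events, horizons beyond the
grid, censoring-KM support exhaustion) raise informative errors or warnings
as contracted in the API docstrings.

## Known limitations

Phantom realism as above; constant per-subject hazard over time (no
time-varying effects); single imaging sequence; no competing risks; the
compact U-Net stands in for a self-configuring segmentation framework (the
claim exercised is encoder-feature transfer, not any specific segmentation
architecture); desk-scale cohorts give wide confidence intervals, so the
package's experiments demonstrate orderings and calibration properties
rather than precise effect sizes.
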