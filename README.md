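# gliorisk

Multimodal recurrence-risk prediction for pediatric low-grade glioma (pLGG):
transfer features from a 3D tumor-segmentation encoder are fused with
clinical covariates in a discrete-time logistic-hazard survival network, with
a full time-dependent evaluation suite and a synthetic phantom cohort
generator with known hazard structure.

## Who this is for

Researchers building or auditing imaging-based survival models for rare
pediatric tumors, where real MRI cohorts are small, non-shareable, and
heavily censored. Because raw clinical MRI cannot be redistributed, the
package ships a seeded phantom generator that emulates a pooled two-site
pLGG cohort — tumors whose geometry drives hazard, protective age and
gross-total-resection effects, site-specific event rates (~20% vs ~36%), and
right-censored discrete-time outcomes — so every pipeline stage and every
metric can be exercised and verified against known ground truth.

## The model

Follow-up is cut into `J` bins with edges `0 = τ₀ < τ₁ < … < τ_J`. For
subject `i` with feature vector `x_i`, a 3-layer fully connected network
emits one logit per bin, and the conditional event probability (hazard) in
bin `j` is

    h_ij = σ(φ_j(x_i)),        S_i(τ_j) = ∏_{m ≤ j} (1 − h_im)

The training loss is the discrete-time negative log-likelihood
(`serial binary regressions`): for an event indicator `d` in bin `k`,

    ℓ = −[ Σ_{j<k} log(1 − h_j) + d·log h_k + (1 − d)·log(1 − h_k) ]

Three variants share the architecture: **clinical** (age z-score + resection
one-hot as sole input), **image** (the 4096-long — 128 at desk scale —
frozen-encoder feature vector), and **multimodal** (image features through
the trunk, clinical vector concatenated onto the final layer's input). The
image features are the deepest encoder activations of a compact 3D U-Net
trained for tumor segmentation, adaptive-average-pooled and flattened; under
the full-size default configuration (5 levels, 32 base channels, growth 2,
pooled grid 2×2×2, input [96, 192, 192]) the vector has 512 × 8 = 4096
entries. The networks are implemented as explicit numpy forward/backward
passes with Adam (see `gliorisk.nn`).

Evaluation: Antolini's time-dependent concordance index with subject-level
percentile bootstrap CIs, cumulative/dynamic 3-year AUC with inverse
probability of censoring weights, 10-bin calibration with expected
calibration error, IPCW (integrated) Brier score, Kaplan–Meier curves,
log-rank tests, and median-threshold risk stratification — all with
enumeration- or hand-verifiable cores (`gliorisk.metrics`,
`gliorisk.cohort_stats`).

## Worked example

Run the full synthetic experiment — generate a 150-subject two-site cohort,
preprocess (bias-correction surrogate, resampling, brain masking, z-score,
framing), train the segmentation U-Net on development subjects, extract
frozen-encoder features, train all three survival variants with 3-fold CV,
and evaluate once on the held-out 30% test split:

```bash
gliorisk run-all --n 150 --seed 7 --out runs/
```

prints the held-out time-dependent concordance per variant

```json
{
  "clinical": 0.6021220159151194,
  "image": 0.636604774535809,
  "multimodal": 0.6790450928381963
}
```

and writes `runs/run_<confighash>/metrics.json` with the full report; for
this seed:

| mode | C^td [95% CI] | 3-yr AUC | ECE | IBS |
|------|---------------|----------|-----|-----|
| clinical | 0.60 [0.38, 0.78] | 0.76 | 0.105 | 0.128 |
| image | 0.64 [0.51, 0.77] | 0.64 | 0.076 | 0.154 |
| multimodal | 0.68 [0.54, 0.81] | 0.68 | 0.088 | 0.142 |

The multimodal > image > clinical ordering reflects the simulated cohort's
design: tumor volume and clinical covariates each carry independent hazard
signal, so fusing them discriminates best. Confidence intervals are wide
because the test split holds only ~45 subjects at this desk scale.

Individual stages are available as subcommands (`simulate`, `preprocess`,
`train-seg`, `extract-features`, `train-surv`, `evaluate`, `finetune`,
`baseline-scratch`) and as library functions; see `docs/methods.md` for the
model and generator details.

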