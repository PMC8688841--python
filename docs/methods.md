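# Methods

## Model

One *domain* is a trials × F matrix of differential-entropy (DE) features
from one subject-session (F = electrodes × frequency bands; 62 × 5 = 310
for the common SEED layout) with integer emotion labels. A transfer task
supplies N labeled source domains and one unlabeled target domain; the
setting is transductive unsupervised adaptation — the target features
participate in training, its labels are used only for final evaluation.

The network is deliberately small, reflecting the low dimensionality and
noisiness of extracted EEG features:

| stage | form | default widths |
|---|---|---|
| common feature extractor (CFE), shared | 3 × (affine + LeakyReLU) | 310 → 256 → 128 → 64 |
| domain-specific feature extractor (DSFE), per source | affine + LeakyReLU | 64 → 32 |
| domain-specific classifier (DSC), per source | affine, no activation | 32 → C |

LeakyReLU (slope 0.01) is used instead of ReLU everywhere so that
negative feature values — common in z-scored DE features — are attenuated
rather than discarded. No dropout, batch-norm or weight decay is used.

Each step draws m samples from every source and from the target. The
objective is

L = L_cls + α·L_MMD + β_eff·L_disc

* **L_cls** — Σ over branches of the mean cross-entropy of the branch's
  source logits against its source labels (mean over the batch, so the
  effective learning rate does not scale with batch size).
* **L_MMD** — Σ over branches of the squared maximum mean discrepancy
  between the branch's source and target DSFE features, estimated with
  the biased V-statistic on equal-size batches (an unbiased U-statistic
  is available behind a flag). The kernel is a multi-bandwidth Gaussian
  RBF: 5 bandwidths in a geometric ladder {¼, ½, 1, 2, 4} × anchor, where
  the anchor is the median pairwise squared distance of the pooled batch,
  recomputed per step and treated as a constant of the step (not
  differentiated). A degenerate batch (zero median) falls back to
  bandwidth 1 with a logged warning. Single-bandwidth RBF and linear
  kernels are available (the linear kernel reduces the estimator to the
  squared mean difference, a useful closed-form oracle), as is a CORAL
  covariance-alignment alternative ‖C_S − C_T‖²_F / 4d².
* **L_disc** — Σ over ordered branch pairs i ≠ j of the mean absolute
  difference of their softmax predictions on the target batch (so N = 2
  counts its pair twice, and N = 1 gives exactly 0). Computed on
  probabilities, not logits, since the branch heads are softmax
  classifiers; softmax/log-softmax use max-subtracted stable forms.
* **α** ramps along training progress p as 2/(1+e^(−10p)) − 1, so early
  optimization concentrates on classification before alignment engages.
  Progress is global_step/total_steps by default (per-epoch progress is a
  config option). β_eff defaults to 0.01·α ("times_alpha" mode); a
  constant-β mode and a delayed activation window
  (`disc_start_fraction`) cover the alternative schedules of the
  discrepancy-weight study.

Optimization is Adam (lr 0.01, β₁ = 0.9, β₂ = 0.999, ε = 1e−8), 200
epochs, batch 256 per domain by default. `steps_per_epoch` is
⌈max_domain_size / m⌉ so every domain is fully visited each epoch; each
domain's sampler exhausts a shuffled permutation before reshuffling and
wraps across epoch boundaries to always deliver exactly m rows. Inference
averages the N branch softmax outputs and takes the argmax
(lowest-index tie-break). Reported accuracy is final-epoch accuracy — no
early stopping and no best-epoch selection, since the protocol has no
validation split; per-epoch accuracy tracking is available when
evaluation labels are passed explicitly, and is labeled optimistic.

All tensor arithmetic runs in float64 on a small reverse-mode autodiff
engine written for this package (`msmda._autodiff`); its gradients are
checked against central finite differences, including through the full
objective (with the kernel anchor pinned, since the anchor is defined as
a non-differentiated per-step constant).

## Protocols

* **cross-session**: for each subject, sessions 1..K−1 are sources and
  session K is the target (one task per subject; 15 tasks of N = 2 on a
  15 × 3 grid).
* **cross-subject**: for each session, subjects 1..S−1 (native file
  ordering) are sources and subject S is the target (one task per
  session; 3 tasks of N = 14).

The fixed last-session / last-subject target is the default; full
leave-one-out rotation is available as an explicitly labeled extension.
Aggregates are mean ± population std across tasks.

## Normalization

Three standardization scopes on a trials × F matrix: *electrode-wise*
(per column; each column is one electrode-band pair), *sample-wise* (per
row), *global-wise* (whole matrix); plus `none` and an `electrode_pooled`
variant that pools each electrode's band columns. The statistic is the
z-score with population (1/n) variance — chosen because the
distance-based MMD bandwidths are scale-sensitive and z-scoring is the
common convention for DE features; min-max is available via
`statistic="minmax"`. Zero-variance slices are centered with the divisor
forced to 1. Two orders for multiple sources: normalize each source
independently then concatenate, or concatenate then normalize with
pooled statistics. Interpretation points that affect exact reproduction
of published normalization grids: the z-score-vs-min-max choice, and the
fact that this package always normalizes the **target** with its own
statistics in both orders (pooled source statistics need not exist at
inference time). For the multi-branch model the sources are never
concatenated, so the two orders provably coincide; the grid annotates
such cells (`order_invariant`) instead of re-running them.

## Synthetic data generator

The generator emulates multi-subject DE feature data at the
extracted-feature level:

1. a shared class structure: per-(class, electrode, band) log-variances
   `base[e,b] + profile[c,b]`, with `base ~ N(0, 0.5²)` and
   `profile ~ N(0, class_separation²)` — class information lives in
   band-specific variance profiles, so distinct bands carry distinct
   class evidence;
2. per-sample features: `DE = ½·ln(2πe·exp(v))` with
   `v = logvar[c,e,b] + N(0, noise_sd²)` — genuine Gaussian differential
   entropies, not arbitrary Gaussians, so the marginal family matches the
   semantics of real DE features;
3. per-domain affine corruption: each domain multiplies column j by
   `exp(N(0, gain²))` and adds `N(0, offset²)`, mimicking inter-subject
   amplitude/impedance differences. Because gains are positive and the
   corruption is column-affine, electrode-wise z-scoring inverts it
   exactly — which is what makes the normalization-effect study
   well-posed on synthetic data.

Domain streams are seeded via per-domain `SeedSequence` children of one
master seed, so adding a domain never perturbs earlier domains' draws.
Labels are balanced across classes. The last domain is the target.

Default shift scales (offset 1.5, log-gain 0.4, noise 0.8, separation
0.5) were calibrated once against an MS-MDA-independent probe: a plain
pooled-source logistic regression should retain roughly 0.6–0.8 target
accuracy (chance ⅓) — genuine but surmountable transfer difficulty,
qualitatively matching raw (un-normalized) cross-subject EEG transfer.
The normalization study uses a strong-gain variant (log-gain 1.0).

What the generator does **not** emulate: temporal autocorrelation and
nonstationary drift within a session, trial-block label structure,
electrode covariance (columns are conditionally independent given the
class), and realistic class imbalance. Passing direction studies on this
generator therefore demonstrate that the implementation behaves as the
method intends under controlled marginal shift — not that the same
margins would be observed on real EEG.

## Study conditions (desk scale)

The direction studies (ablation benefit of MMD alignment, accuracy vs
source count, normalization effect) run at a reduced problem size chosen
as this package's standard single-CPU configuration: 16 electrodes × 5
bands (80 features), 300 samples/domain, backbone 80 → 64 → 32 with
16-dim DSFE, 40 epochs, batch 64 (`msmda.studies.STUDY_NET`). Five
paired seeds per comparison; contrasts share seeds and data so
differences reflect the method. Seed-level comparisons use a one-sided
sign test (ties dropped) plus the mean difference, rather than a
single-run threshold, because training is stochastic across seeds.

## Numerical choices and degenerate cases

* Biased MMD estimates are clipped at 0 (the V-statistic is
  mathematically non-negative; tiny negative values are float noise).
* Softmax ties at prediction time break to the lowest class index.
* Constant feature columns normalize to zeros (divisor forced to 1).
* Model initialization is uniform fan-in (±1/√fan_in), per-branch
  independent, fully determined by one integer seed; training is
  deterministic given the seed up to BLAS reduction order.
* A non-finite total loss aborts training with the offending step.

## Known limitations

* CFE hidden widths (310 → 256 → 128 → 64) are a smooth-taper choice;
  only the input/output widths and the 3-affine-layer depth are fixed by
  the reference recipe. "3-layer" is read as three affine layers.
* The kernel family for the MMD is a convention choice (the DAN-lineage
  multi-RBF ladder); published accuracy tables may depend on it.
* The source-combine baselines implement the alignment losses of the
  DDC/DAN/DCORAL family on this package's backbone, not those papers'
  original architectures — adequate for strategy contrasts, not for
  quoting those methods' numbers.
* Real SEED/SEED-IV reproduction requires the registered datasets and is
  provided as a documented path (see README), never asserted in tests.
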