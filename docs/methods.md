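# Methods

`connclass` implements a network-centric pipeline for classifying subjects
from resting-state functional connectivity: feature extraction against a
fixed 16-network / 56-node atlas, SVM-AdaBoost classification with recursive
feature elimination under leave-one-out cross-validation (LOOCV), and
significance assessment by random-label nulls and feature-recurrence counts.
This note records the model, the defaults and their rationale, and the
numerical and design choices made where the procedure was genuinely open.

## Atlas and feature spaces

The packaged atlas (`data/rsn16_nodes.tsv`) lists 56 node regions in 16
resting-state networks (RSNs), with Talairach centroids and cluster volumes
carried as metadata only. Row order is the canonical feature order. Three
single-node networks (Visual-1, Visual-3, Visual-4) naturally contribute no
within-network pairs; pair enumeration handles them without special-casing.
The atlas fixes the three feature spaces:

* **REP** (56): mean of the subject's standardized network map over each
  node's voxels — how representative a node is of its parent network.
* **B-RSN** (120 = C(16,2)): Pearson correlation between network
  time-course pairs.
* **W-RSN** (119 = Σ C(n_k,2)): Pearson correlation between node-mean
  time-course pairs within each network.

Feature names encode identity (`REP:ECN:9`, `B:SM|AUD`, `W:ECN:9-11`) so
per-fold selections are joinable across runs.

## Preprocessing

Order: censor detection → nuisance regression → band-pass → censored-row
removal by correlation consumers. Censoring flags the **later** volume of
any consecutive pair whose head position changes by more than 0.3 mm
(translation) or 0.3° (rotation); marking only the later volume is a
convention choice, isolated behind `CensorMask` so it is swappable.
Nuisance regressors are the first 3 principal components of the white-matter
voxel ensemble, 3 of the CSF ensemble (computed on kept volumes only, so
spike variance cannot leak into them; deterministic sign convention:
largest-magnitude loading positive), and the 6 motion parameters. The OLS
fit includes an intercept (correlations are translation-invariant, so this
is harmless and numerically safer) and is estimated on kept volumes only.
The band-pass (0.01–0.15 Hz) is an ideal frequency-mask filter with DC
removed — chosen over an IIR design because its pass/stop behavior is
exactly testable. Whether filtering precedes or follows nuisance regression
is not dictated by the procedure being modeled; the implemented order
(regress → filter → drop) is a package decision. Neither regression nor
filtering changes the number of rows.

## Dual regression and feature extraction

Stage 1 regresses each volume jointly on all 16 template maps (multiple
spatial regression), yielding 16 time courses; stage 2 regresses each voxel
series (kept volumes, with intercept) on all 16 time courses, yielding 16
coefficient maps. Two standardizations of the stage-2 maps are available:
the default divides each coefficient by its regression standard error (a
Z/t-statistic map); the alternative standardizes each map spatially to mean
0 / SD 1. Neither is asserted to be canonical — the choice is exposed as
`standardize=`. B-RSN time courses come from the same stage-1 regression
(one computation, two consumers). A "separate fits" reading of the spatial
regression exists in the literature; joint fitting is the default because
it is the standard dual-regression formulation. Correlations are computed
on censored-row-deleted series; no Fisher transform is applied.

## Classification

Per LOOCV fold: standardize features on the 41 training subjects (training
mean/SD, population SD; min-max available via `scaling="minmax"`), apply the
same transform to the held-out subject, run RFE on the training fold, train
AdaBoost on the retained features, predict the held-out subject.

* **Linear SVM**: soft margin, C = 1, libsvm via scikit-learn, per-sample
  weights supported.
* **RFE**: retained count = ceil(n_features · (1 − elim_frac)) — so 119
  features at 90% elimination retain exactly 12, and 50% retains 60. Each
  iteration drops 10% of the *surviving* features with the smallest
  |weight|, ties broken by dropping the lower canonical index first; the
  last step never overshoots the target. `elim_frac = 0` is the identity.
* **AdaBoost**: discrete boosting with re-weighting (not re-sampling):
  uniform initial weights, per round fit a weighted SVM, weighted error ε,
  vote α = ½ ln((1−ε)/ε), multiplicative re-weighting w ← w·exp(−α·y·h),
  renormalize. ε = 0 stops early with the member kept at a capped α
  (ε floored at 1e−10) — separable training folds are common at n = 41 and
  must not produce infinite votes. ε ≥ 0.5 discards the member and stops;
  if that happens in round 1 the one member is kept with α = 1 so the
  ensemble still predicts (it then equals the plain SVM). `n_rounds`
  defaults to 10 and is exposed in configuration. Decision ties (vote sum
  exactly 0, or a lone member's decision exactly 0) resolve to the positive
  class — one convention shared by member and ensemble.
* **Metrics**: accuracy = (TP+TN)/all. Precision defaults to the standard
  TP/(TP+FP); a TP/(TP+TN) variant is available as
  `precision_mode="as-printed"` because that formula also circulates in
  this literature. With no positive predictions, standard precision is
  reported as 0.

The whole fold chain is deterministic given its inputs; `seed` parameters
exist for interface symmetry and for the stochastic stages only.

## Significance

**Random-label null**: each repetition draws an independent fair-coin label
per subject ("bernoulli", default) or shuffles the true labels
("permutation", preserving the 21/21 split), then reruns the entire LOOCV
pipeline on the same feature matrix. Degenerate labelings (a class with
fewer than 2 members) are redrawn and logged. Under the Bernoulli null the
held-out label is independent of the prediction, so the null accuracy is
centered at ½ exactly. The observed metric is compared by a one-sided
upper-tail Z-test and by the strict criterion actual > mean + 2·SD.

**Feature recurrence**: counts how many of the n_folds per-fold selections
contain each feature. Under uniform selection of n_keep from n_total the
count is Binomial(n_folds, q); the default takes q = n_keep/n_total
(12/119 under 90% elimination of 119 features — the appearance probability
of a specific feature when 12 are retained uniformly), with q = 1/n_total
available as `mode="literal"` for comparison with the cruder convention.
The reported p is the exact upper tail P(X ≥ k).

**Known limitation**: LOOCV folds share all but one training subject, so
per-fold selections are strongly positively correlated and the
independent-fold binomial null is anti-conservative — on pure-noise
features roughly 10% of features reach p < 0.01 rather than 1%. The
recurrence p-value should be read as a descriptive ranking statistic, not
a calibrated error rate; the package's own power check therefore compares
*mean recurrence counts* of perturbed versus unperturbed edges rather than
thresholding p-values.

## Synthetic cohorts

The generator produces the data structure the analysis assumes, not scanner
realism: no hemodynamics, no spatial smoothness, no slice timing, and no
between-subject variability in the population covariance (every subject of
a group shares one generative law). Defaults: 21 subjects per group, 180
volumes at TR = 2 s (chosen so post-censoring counts land near ~174–178
surviving volumes), 8 voxels per node, 30 WM + 30 CSF voxels, motion-spike
probability 0.02 per TR.

Node signals are band-limited (0.01–0.15 Hz) Gaussian processes synthesized
in the frequency domain — matching the band-pass band so preprocessing does
not destroy signal — and mixed through the Cholesky factor of an exactly
specified covariance: within-network node pairs have population correlation
r0 = a²/(a² + 1 + σ²/P) of their voxel-averaged time courses (a =
`base_coupling` = 0.8 giving r0 ≈ 0.36, σ = voxel noise SD, P = voxels per
node), cross-network correlation 0. Group-1 subjects draw from a covariance
in which each configured effect edge is raised to r0 + `effect_size`; the
calibration accounts for voxel-noise attenuation, so the group difference
in sample correlations equals `effect_size` in expectation (verified by
Monte Carlo). Direct covariance specification was chosen over scaling
shared-signal couplings because coupling scales perturb every pair among
the touched nodes, not just the configured edges, and over per-edge additive
latents because those cannot reach the target when edges share nodes (the
variance inflation outpaces the covariance). Requests that would make the
covariance non-positive-definite raise an error.

WM/CSF ensembles are linear mixtures of three dedicated latent signals per
tissue plus white noise, so their leading principal components are
well-defined. Motion is a slow random walk (step SD 0.02 — far below the
censoring threshold) with occasional super-threshold step changes in one
randomly chosen column, exercising the consecutive-volume censoring rule
directly.

Because subjects within a group are exchangeable draws from one law, the
injected effect is easier to detect than a comparable effect in real
cohorts (no between-subject heterogeneity); passing the power check
demonstrates the machinery is wired correctly, not that real smokers are
classifiable at these accuracies.

## Problem sizes used in tests and the acceptance script

Chance calibration runs 10 cohorts (seeds 0–9) at the full 21+21 × 180
scale with 100-repetition nulls per classifier at 0% elimination (the
cheapest level, where RFE is the identity and cannot add selection
variance). The power check uses one 21+21 cohort with a 0.3 effect on the
10 ECN/FP edges and a 100-repetition null at 90% elimination. The
recurrence tail is cross-checked against 10⁷ Monte-Carlo draws. Unit tests
use smaller cohorts (6–8 subjects, 64–80 volumes) that preserve the full
structure. The acceptance script mirrors these sizes with 100 permutations.

## Reproducibility

Every stochastic stage consumes a seed; per-stage seeds are split from the
master seed through independent substreams, so changing the number of
permutations never perturbs the simulated cohort. Identical configurations
reproduce bit-identical cohorts, reports, and null distributions, and the
pipeline records a configuration hash in its provenance block.
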