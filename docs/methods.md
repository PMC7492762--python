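# Methods

This note documents the models, the synthetic-data calibration, the
numerical choices, and the places where the design was genuinely open.

## Latent-class piecewise-exponential proportional-hazards mixture

Patient `i` has covariates `x_i`, observed time `t_i` (days) and event
indicator `δ_i`.  Conditional on latent class `k` (probability `π_k`,
independent of covariates) the hazard is

    h_k(t | x) = h0_k(t) · exp(β_k · x),

with `h0_k` piecewise constant on `B` bins whose shared cut-points sit at
quantiles of the observed event times.  The observed-data log-likelihood is
`Σ_i log Σ_k π_k L_ik`, where `L_ik` is the class-conditional
piecewise-exponential likelihood.  Writing `Δ_ib` for patient `i`'s exposure
time in bin `b` and using the event-bin indicator, `log L_ik` is the usual
Poisson-likeness of piecewise-exponential survival; an event that falls
exactly on a cut-point is attributed to the interval it closes, which keeps
the likelihood identical to a person-time-expanded Poisson regression (the
K = 1 oracle used in the tests).

**EM.**  The E-step computes responsibilities; the M-step sets `π` to the
mean responsibility and, per class, alternates the closed-form
occurrence/exposure update for the baseline rates with damped Newton steps
for `β_k` on the responsibility-weighted Poisson objective (three inner
cycles, step-halving on the surrogate).  Every conditional update increases
the EM surrogate, so the observed log-likelihood is non-decreasing — a
property the tests assert on the recorded iteration history.  Convergence:
relative log-likelihood change below `tol` (default 1e-8); default 20
restarts (the tests and pipeline use fewer), initialized from k-means on
`(log t, δ, x)` plus restart-dependent Dirichlet jitter.

**Labelling.**  The mixture likelihood is invariant to permuting class
labels, so after fitting, classes are ordered by decreasing model-implied
median survival at the mean covariate vector: "class 1" is always the
good-prognosis class.  MAP ties break to the lowest class index.

**Model selection.**  `K` and the number of baseline bins are chosen by
minimum BIC = `−2·loglik + n_params·log n` with
`n_params = (K−1) + K·B + K·p`, a Laplace-type proxy for Bayesian model
selection.  The full candidate grid, including failed cells, is kept in the
model metadata.

**Standard errors.**  Wald SEs for `β` come from a robust (sandwich)
variance `I⁻¹ V I⁻¹`: `I` is the observed information of the full mixture
log-likelihood (central finite differences of the analytic score over the
mixing logits, log rates and betas), and `V` is the empirical outer product
of per-subject scores.  Bare observed-information intervals proved
anti-conservative in simulation — the class membership is estimated, and
its uncertainty propagates into the coefficients — while the sandwich form
restores at-or-above-nominal coverage.  Singular information flags the
affected entries rather than failing.

## Synthetic cohort generator and the `coin-os` preset

The generator draws class labels from `π`, covariates from class-conditional
distributions, event times by cumulative-hazard inversion of the class's
piecewise-exponential hazard times `exp(β_k·x)`, and censors at the minimum
of an administrative horizon and an independent uniform dropout time.  All
randomness flows from one integer seed through named substreams.

The default preset encodes a 398-patient two-arm advanced colorectal cancer
cohort:

- `π = (0.156, 0.844)`; class 1 is the small good-prognosis class.
- Class-1 treatment log-HR `ln 0.43`; class-2 FRET log-HR `ln 0.64` per SD
  of the cohort FRET distribution; other coefficients zero.
- Piecewise baseline rates on cut-points (0, 300, 700, 1200) days,
  calibrated so the marginal class medians are ≈1624 and ≈461 days
  (verified at n = 40 000 during calibration: 1620 / 460).
- Administrative horizon 2200 days plus uniform(0, 9000) dropout, giving
  ≈20% censoring overall.
- Covariate class contrasts (treatment-arm share, RAS mutation rate, FRET
  and FRET×HER3 distributions) follow the characteristic between-class
  differences of such cohorts.

**FRET-efficiency calibration.**  The cohort-level efficiency distribution
must have mean 1.6% with quartiles 0.18% and 2.7%.  No gamma (or Weibull or
log-normal) family fits those three numbers — the upper quartile exceeds
what a unimodal gamma with that mean can reach — so each class mixes a
"no-dimer" component, Normal(0, 0.466%) (negative measured efficiencies are
kept, as in the quantification module), with a dimer-positive Gamma(shape 5)
component.  With class means 1.0% and 1.711% and a common no-dimer fraction
0.3843, the mixture reproduces mean/quartiles to three digits; the constants
are frozen in `FRET_CALIBRATION`.  The within-class distribution is a
modelling choice: only cohort-level summaries are published.

**The `separation` parameter.**  Parameter-recovery experiments need a
generator that lies *exactly* in the fitted model class.  Because the
fitted mixture assumes covariate-independent mixing weights, a generator
whose covariate distributions differ by class induces covariate-dependent
membership, and the maximum-likelihood pseudo-truth drifts away from the
generating `π` (we measured `π̂₁ ≈ 0.23–0.30` against a generating 0.156 at
n = 2000 — a misspecification effect, not an estimation error; the same
tension exists in any real analysis of this kind).  The recovery variant
(`separation ≠ 1`) therefore (a) scales the log hazard ratios and the
between-class log baseline-rate gap by the given factor, (b) extends the
follow-up horizon and dropout window proportionally (a slower class needs a
longer trial to be resolved), and (c) pools the covariate marginals across
classes.  The default `separation = 1` keeps the realistic class contrasts.

**FLIM scenes.**  Matched D/DA image pairs carry per-region planted
efficiencies: D pixels are `τ_D` + Gaussian noise, DA pixels
`τ_D(1 − E_true)` + noise; a stated fraction of pixels instead carries a
short autofluorescence lifetime (default 0.8 ns vs donor 2.6 ns), and the
contaminated-pixel map is returned as ground truth.  Decay histograms are
multinomial draws from an exactly discretized truncated exponential.  Not
emulated: multi-exponential decays, instrument-response convolution,
spatial tissue texture, slice-to-slice registration error — so passing
image-chain tests demonstrates correctness of the estimators, not
robustness to those real-data effects.

## FRET quantification

Region efficiency is computed from the ratio of region-mean lifetimes,
`E = 1 − mean(τ_DA)/mean(τ_D)` (not the mean of pixel ratios), matching the
definition used with average region lifetimes.  The autofluorescence filter
clears mask pixels whose donor lifetime falls outside a plausibility window
(default 1.5–4.0 ns; the published filter's exact parameters are not
stated, so the window is configurable).  Negative efficiencies are retained
and flagged `NEGATIVE_E` — clamping would bias cohort summaries; regions
with fewer than 10 surviving pixels are flagged `LOW_PIXEL_COUNT` and
reported missing.  Patient-level covariates are pixel-weighted means over
valid regions; patients with no valid region stay in the table as missing.
The monoexponential lifetime MLE maximizes the binned truncated-exponential
likelihood by bounded 1-D search; a flat histogram (lifetime → ∞) returns
`inf` with a non-convergence warning, and a single occupied bin raises.

## Covariate reduction

Backwards elimination under repeated stratified K-fold cross-validation
(defaults 5 folds × 20 repeats).  Inner fits are ridge-penalized
(Gaussian-prior MAP): Breslow partial likelihood for survival outcomes via
a vectorized Newton solver written for the many-small-fits workload (the
library Cox fitter is the cross-check in tests, not the inner engine), or
`scikit-learn` ridge logistic for class labels.  Scores are mean held-out
partial log-likelihood per event, or negative log-loss.  At each step the
covariate whose removal least degrades the mean held-out score is dropped;
elimination stops when even the best removal degrades the score by more
than `stop_rule` (default 1) standard errors of the paired fold-wise
difference — a one-standard-error-style rule, since the published stopping
criterion is not stated.  `selection_frequency` replays the consensus
elimination path against each repeat's own folds and stopping decision, so
it reports the fraction of repeats in which a covariate survived.

## Signature and thresholding

Weights are ridge-logistic MAP coefficients for class-2 membership on
standardized covariates (missing values imputed at training means with
indicator columns); the constant `c = −mean(w·x̃)` makes the training-score
mean exactly zero.  How the published weights were obtained is not stated
beyond covariate reduction; ridge logistic is the minimal class-prediction
analogue.  The ROC is evaluated at every observed cut-point with the rule
`score > θ ⇒ class 2`; AUC is the trapezoid area; the Youden threshold
takes the smallest maximizer on ties (deterministic, favours sensitivity).
Standardization and imputation parameters are frozen from the training
cohort, so validation scoring is blind.  Evaluation reports the prognostic
split (classes within the control arm, to avoid treatment confounding) and
predictive splits (arms within each class) with Kaplan-Meier tables and
log-rank p-values.

## Survival statistics

Kaplan-Meier, log-rank and Cox wrappers are backed by `lifelines`.  Median
CIs use the log-log (exponential Greenwood) transform; with an even number
of uncensored subjects the median is the lower of the two central event
times (the first time S(t) ≤ 0.5).  Cox ties use the Efron approximation.
Monotone-likelihood cases (all events in one covariate level) are flagged
`DEGENERATE` rather than reporting a spurious estimate.

## Permutation overlap test

The statistic is the alignment-maximized co-assignment count: the maximum
over one-to-one class matchings (assignment problem on the cross-table) of
the number of patients placed in matched classes — invariant to relabelling
and defined for unequal class counts.  The null permutes one labelling
uniformly, preserving both margins exactly.  `p = (#{null ≥ obs}+1)/(N+1)`
never returns 0; its floor `1/(N+1)` expresses "less than 1 in N".  Because
the statistic is integer-valued, p is slightly conservative
(super-uniform) at small n and few classes; calibration checks therefore
use n = 1000 with 3×3 classes, where the discretization is negligible.

## Problem sizes and defaults used in the test suite

Simulation-heavy checks run at the sizes their questions require and no
larger: distribution calibration at n = 398 × 200 seeds; parameter recovery
at n = 2000 × 100 seeds (6 EM restarts); BIC selection at n = 1000 × 50
seeds per truth; reduction at n = 600, 5 × 10 CV × 25 seeds; log-rank
calibration at 1000 null replicates; permutation-null calibration at 500
seeds × 999 permutations.  The acceptance script averages estimation-based
quantities over 20 replicate cohorts of n = 398 and uses 100 000
permutations for the overlap test.

## Known limitations

- Mixing weights do not depend on covariates; when the data-generating
  membership does (the default preset), the fitted `π` is a pseudo-true
  value, not the generating share — see the `separation` discussion above.
- The EM/BIC machinery is a maximum-likelihood surrogate for a fully
  Bayesian latent-class analysis; no posterior over partitions is produced.
- At weak separation (the realistic n = 398 preset), per-cohort estimates
  of class-specific effects are noisy and MAP shares are prior-dominated;
  the acceptance script averages over replicates rather than pretending a
  single cohort is decisive.
- The imaging model omits instrument response, multi-exponential decay and
  registration error (above), and the reduction stop rule and signature
  fitting model are documented choices where the source analysis is
  unspecified.
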