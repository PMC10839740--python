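# Methods

## The model

For each region of interest (ROI) `r`, cortical thickness `y` (mm) of scan
`i` is modelled as a linear function of age with batch-specific parameters:

    y_i     = alpha_b(i) + beta_b(i) * x_i + eps_i,   eps_i ~ N(0, sigma_b^2)
    alpha_b ~ N(mu_alpha,    tau_alpha^2)
    beta_b  ~ N(mu_beta,     tau_beta^2)
    log sigma_b ~ N(mu_logsigma, tau_logsigma^2)

`x` is age standardized by the reference-training mean and SD (the same
affine transform is frozen into every later prediction so that prior scales
are covariate-scale invariant).  A *batch* is a site x sex cell: the full
cross is used rather than additive site and sex terms, so every scanner
gets its own male and female intercept, slope, and noise level.  The noise
is hierarchical on the log scale, which guarantees positivity and yields a
transferable "variance of the variance" hyperparameter (`tau_logsigma`).
ROIs are fitted independently; there is no spatial coupling.

Deviation scores are `z = (y - pred_mean) / pred_sd` with

    pred_mean = E[alpha_b + beta_b x]
    pred_sd^2 = Var[alpha_b + beta_b x] + E[sigma_b^2]

i.e. the full Gaussian predictive approximation, combining posterior
parameter uncertainty with the noise level.  Parameter uncertainty matters
for tail calibration precisely when adaptation sets are small; a
noise-only mode (`predictive="noise"`) exists for sensitivity analysis.
One consequence worth knowing: because pred_sd is slightly inflated by
parameter uncertainty, the fraction of held-out controls beyond |z| = 2
sits a little *below* the Gaussian tail value 2.28% (about 2.2% with
100-scan adaptation sets), rather than at the nominal rate.

## Inference

The posterior is sampled with a blocked Gibbs sampler written for this
model (2 chains x 1,000 draws after 1,000 warmup by default; all updates
vectorized over batches and ROIs):

* `(alpha_b, beta_b)` — exact bivariate-normal conjugate draws;
* `mu_alpha, mu_beta, tau_alpha, tau_beta` — *collapsed* updates: with x
  centred within batch, the per-batch OLS mean and slope have a
  closed-form 2x2 Gaussian marginal once the batch effects are integrated
  out, so the mu's are drawn exactly and the log-tau's move by
  random-walk Metropolis against that marginal.  Collapsing removes the
  funnel coupling between hyperparameters and batch-level deviations that
  makes centred Gibbs mix poorly when tau is small;
* `log sigma_b` — adaptive random-walk Metropolis;
* `mu_logsigma, tau_logsigma` — centred conjugate/Metropolis updates plus
  two non-centred moves (a joint translation of the whole hierarchy and a
  rescaling of the deviations with tau), repeated three times per sweep
  because this hierarchy admits no analytic collapse;
* proposal scales adapt during warmup toward 0.44 acceptance.

Convergence is gated on split-chain rank-normalized R-hat < 1.05 over all
stored parameters (via arviz); a non-converged fit is returned with its
flag down and a warning, never silently.  Fixing the seed reproduces the
draws exactly.

Default hyperpriors are weak and scale-aware: `mu_alpha ~ N(mean y,
10 sd y)`, `mu_beta ~ N(0, 10 sd y)`, `tau_alpha, tau_beta ~
HalfNormal(5 sd y)`, `mu_logsigma ~ N(log sd y, 2)`, `tau_logsigma ~
HalfNormal(1)`.  Scaling by sd(y) keeps the model equivariant under
affine re-units of the response (mm vs um), which is tested.

## Transfer to unseen scanners

`summarize_hyperposterior` reduces a reference fit to twelve numbers per
ROI (posterior mean and SD of the six hyperparameters; SDs floored at
1e-6 of the mean scale so downstream priors stay proper).  Only this
summary crosses the site boundary — no subject-level data — which is what
makes the scheme usable in federated settings.  `build_transfer_priors`
turns it into informed priors: Normal for locations, zero-truncated Normal
for scales.  During adaptation the hyperparameters are re-sampled under
those informed priors jointly with the new batches' parameters, so
reference uncertainty propagates; a frozen point-estimate mode exists for
comparison, as does a prior-only mode (no adaptation data) in which
predictions revert to the hyperprior means.

Target batches are keyed per measurement wave by default (`per_wave`),
not per physical scanner: a wave-specific shift (e.g. a scanner software
upgrade between waves on the same hardware) is then absorbed into that
wave's intercept, where a `per_scanner` definition would smear it across
waves — visible as opposite-signed median-z offsets in the two waves
sharing a scanner.

Adaptation sets are sampled without replacement per batch, after
withholding the validation rows (all scans of subjects measured in all
three waves, and wave-1 scans inside the 8.6-10.7 y overlap window).  The
withholding is built into the sampling function rather than left to
callers, to make leakage impossible.  The `age_uniform` strategy
stratifies a batch's age range into equal-width bins and draws one scan
per bin — useful when a wave's age distribution is narrow and peaked.

With the target's narrow age range mapped through the reference age
standardization, the extrapolated intercept (at the lifespan mean age) and
the slope remain prior-dominated at any realistic adaptation size; only
the fitted mean near the batch's own ages and the noise level converge to
their MLEs.  That is the intended behaviour — the transferred slope prior
is what the target cohort cannot estimate for itself — and the
consistency tests check exactly the identifiable functionals.

## Evaluation metrics

All with population (1/n) moments:

* EV   = 1 - Var(y - yhat)/Var(y)  (residual variance is mean-removed);
* SMSE = mean((y - yhat)^2)/Var(y), so the trivial mean predictor scores 1;
* MSLL = mean Gaussian negative log predictive density minus that of a
  trivial Gaussian fitted to the *adaptation* targets of the same ROI
  (never the test targets); negative is better.

The adaptation-size sweep reserves a fixed per-batch pool (largest size
plus a 100-row margin, at most two thirds of the batch) drawn once from
the master seed; every replicate samples inside the pool so all cells
share one common test remainder.  The plateau size is the smallest size
whose mean MSLL is within 0.01 nats of the largest size's mean,
one-sided: a size that is *better* than the largest size by more than
0.01 nats counts as plateaued (a two-sided reading would absurdly label
it non-converged).

The raw-vs-z overlap-window comparison uses the pooled-variance Student
t-test (df = n1 + n2 - 2).  Per-ROI extreme-deviation contrasts are
descriptive percentages with binomial SEs; no multiple-testing correction
is applied, deliberately.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes — and is the
ground truth against which recovery and calibration are tested:

* **Reference**: 20 sites x 150 subjects (desk-scale stand-in for a
  lifespan collection), age windows spread over 5-100 y with widths that
  guarantee joint coverage of the 6-17 y target range; batch = site x sex.
* **Target**: three waves on two scanners (wave 1 on scanner A at 6-10 y,
  waves 2 and 3 on scanner B at 9-12 and 13-17 y), 400 subjects per wave
  by default; wave-2 ages triangular (peaked) to motivate age-uniform
  adaptation sampling; 10% of subjects measured in all three waves with
  strictly increasing ages; an 8.6-10.7 y overlap window populated by
  both scanners.
* **Parameters** (defaults, chosen once at magnitudes typical for
  cortical thickness): intercepts 2.2-2.75 mm across 10 ROIs, slopes
  -0.016 to -0.007 mm/y (thickness declines with age), sex offset
  0.03 mm, between-batch SDs tau_alpha = 0.10 mm and tau_beta =
  0.002 mm/y, baseline noise 0.12 mm modulated by ROI area as
  (area/mean area)^-0.25 (small parcels are noisier), tau_logsigma =
  0.15, subject-level random intercept omega = 0.15 mm, wave-3 additive
  offset 0.05 mm (software-upgrade mimic), optional deterministic
  per-scanner offsets, preterm fraction 6% with mixed-sign per-ROI shifts
  (+-0.2 to 0.25 mm on four ROIs).  Site-effect magnitudes deliberately
  dominate one wave's biological change, so raw trajectories are visibly
  scanner-confounded while z trajectories are not.

The subject intercept `u_j` is in the generative truth but deliberately
absent from the fitted model; its variance is absorbed into the batch
noise.  This is what makes within-subject z stable across waves (the
subject carries their own offset through every scan) and it is why the
truth-based oracle z uses sqrt(sigma_b^2 + omega^2) in the denominator.

What the generator does **not** emulate: nonlinear lifespan trajectories,
non-Gaussian residuals, motion/quality artifacts beyond the wave offset,
spatial correlation between ROIs, or missing data.  Passing tests
therefore demonstrate the statistical machinery (partial pooling,
transfer, calibration, site-effect removal) under the model's own
assumptions, not robustness to their violation on real images.

## Numerical choices and degenerate inputs

* log tau clipped to [-13, 4], log sigma to [-13, 6]; residual sums of
  squares floored at 1e-12; 2x2 solves guarded against singular
  determinants.
* Hyperposterior SDs floored at max(1e-6 |mean|, 1e-8).
* Batches need >= 3 observations; fits need >= 2 batches unless
  explicitly single-batch; missing thickness is rejected (the analysis
  requires complete ROI data).
* Zero target variance makes EV/SMSE undefined: flagged NaN with a
  warning rather than an exception.
* Models serialize from posterior summaries (sufficient for prediction),
  so save/load round-trips reproduce predictions bit-identically.

## Problem sizes used by the shipped tests and acceptance script

The acceptance computations use the default 10-ROI reference (3,000
scans) and a 7,800-scan target (2,600 subjects per wave), leaving ~5,300
held-out control scans after withholding and adaptation; the sweep runs
the full {5,...,300} grid with 10 replicates at reduced sampler settings
(2 x 500/500).  The validation contrasts use 20 fixed-seed replicates
each.  These sizes are the package's desk-scale stand-in for the
42,993-scan reference collection and 6,285-scan target of a full study.

## Known limitations

* Linear mean only; no spline/SHASH likelihoods for lifespan curvature.
* The transfer approximates the hyperposterior by independent (truncated)
  Gaussians; full-covariance transfer is an extension point.
* The |t| < 2 criterion used in the overlap validation has an intrinsic
  ceiling: even perfectly calibrated scores exceed it in ~4.5% of
  replicates.
* Extreme-deviation contrasts are descriptive; no inference across ROIs.
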