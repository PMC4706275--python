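# Methods

## Structural model

Concentration at clock time `t` (decimal hours, everything interpreted
modulo 24 into [0, 24)) is `Base + Circadian(t)`. Three rhythm shapes are
implemented:

* **stretched cosine** (the model of interest): the cosine phase `τ`
  advances linearly from 0 to 12 over the peak-to-nadir interval
  `L1 = (t_min − t_max) mod 24` and from 12 to 24 over `L2 = 24 − L1`,
  so `Amplitude·cos(2πτ/24)` attains `+Amplitude` exactly at `t_max` and
  `−Amplitude` exactly at `t_min` for any asymmetry. `L1 = 12` recovers
  the plain cosinor identically (a property test asserts machine-precision
  agreement).
* **standard cosine**: `Amplitude·cos(2π(t − φ)/24)`, the symmetric
  comparator.
* **double cosine**: a 24-h plus a 12-h harmonic — the conventional
  two-harmonic cosinor, included purely as a comparator for model
  selection.

Degenerate geometry (`t_max ≡ t_min` mod 24) raises an error in user-facing
code paths; inside samplers such parameter vectors simply carry zero
likelihood.

## Statistical model

Individual parameters are log-normal, `P_j = P·e^{η_j}`, including the
two clock times (multiplicative on decimal hours, re-wrapped into
[0, 24)). The baseline random effect may pass through a Box–Cox
transform `η* = ((e^η)^{θ₁} − 1)/θ₁` before exponentiation; `θ₁ < 0`
bounds `η*` above by `−1/θ₁` and induces negative skew. `|θ₁| < 1e−8`
switches to the analytic identity limit. Between-subject covariance is
block-diagonal — {t_max, t_min} and {Amplitude, Base} blocks with free
within-block correlation, zero across blocks. Residual error is
proportional, `y = f·(1 + ε)`, `ε ~ N(0, σ²)`, so `y | η ~ N(f, σ²f²)`;
predictions must be positive, and parameter vectors whose trough goes
non-positive have zero likelihood.

Covariates act multiplicatively on the typical baseline:
`Base_i = Base·(1 + θ_sem·sem1_i)·(1 + θ_age·(age_i − ref)/10)`,
matching effects reported as percentages; an additive combination of the
fractional effects is available behind `covariate_form="additive"`.
Continuous covariates are centered on the dataset median unless a
reference is pinned in `ModelConfig.covariate_refs` (reproduction runs
pin age at 49.9 y). Height may not be tested alongside BMI (it is a
component of BMI). Dichotomous *semester* covariates derive from the
season of sampling: winter Dec 21–Mar 19, spring Mar 20–Jun 19, summer
Jun 20–Sep 21, fall Sep 22–Dec 20; semester 1 = winter/spring,
semester 2 = fall/winter.

## Estimation

SAEM with the subject's individual log-parameters `φ` as latent
variables. Given `φ`, the data likelihood does not involve the
population fixed effects, which keeps the M-step mostly closed-form:

* E-step: vectorized per-coordinate random-walk Metropolis over all
  subjects simultaneously (default 2 sweeps/iteration), proposal scales
  adapted toward 35% acceptance during burn-in, followed by one
  prior-independence Metropolis pass per coordinate (each eta proposed
  from its marginal prior).  The independence kernel matters for
  high-shrinkage coordinates, where random walks mix too slowly to hold
  prior-level dispersion and would otherwise drag the variance estimate
  down.
* M-step: stochastic-approximation averages for the plain log-normal
  typical values (means of `φ`), the block-projected second moment of
  `η` for Ω (annealed diagonal floor during burn-in against early
  collapse), and the mean squared proportional residual for σ². The
  baseline prior parameters (typical Base, covariate fractions, Box–Cox
  shape) fall outside the exponential family and are updated by a short
  warm-started Nelder–Mead maximization of the current draws' prior
  likelihood each iteration, blended with the same step sizes.
  Structural parameters carrying no random effect are refined the same
  way against the data likelihood; a model with no random effects at all
  degenerates to properly converged maximum likelihood (the final polish
  runs only in that case — with random effects a conditional polish
  would bias the marginal optimum).
* Schedule: default 300 burn-in iterations (step 1) + 150 averaging
  iterations (step 1/k); `SaemSettings.fast()` (160 + 80) is used for
  bootstrap replicates and search loops.

Starting values come from a deterministic coarse grid search over
`(t_max, L1)` on the pooled data with closed-form baseline/amplitude
regression — hourly-summary heuristics proved unstable on sparse
designs and sent different model variants into different local optima.

**OFV.** −2 log marginal likelihood by per-subject adaptive importance
sampling: a pilot round from a multivariate-t proposal centered on the
final MCMC state of each subject (covariance = batched Gauss–Newton
curvature + prior precision), then a fresh final round from the pilot's
weighted posterior moments. The proposal is a defensive mixture (local
t, 3×-wide t, and the prior itself), which bounds the importance weights
and guarantees finite variance; the final estimate uses only the fresh
draws, so it is unbiased given the adapted proposal. Monte-Carlo SE is
reported from the per-subject effective sample sizes. A toy-model test
checks agreement with a tensor Gauss–Hermite quadrature oracle.
Posterior-mode (Laplace) centering was tried and rejected: for subjects
with near-zero individual amplitude the curvature at the mode is much
sharper than the posterior's heavy tails and the estimator goes
materially biased.

**Model comparison.** Nested models are compared by LRT on OFV
differences. For covariate steps, the difference is computed *paired*:
both models' integrands are evaluated on one common set of per-subject
draws, so Monte-Carlo errors largely cancel; three paired replicates
give an empirical SE, and a step is accepted only when the OFV drop
clears the chi-square cutoff by three such SEs (guarding against
Monte-Carlo noise masquerading as improvement).

**Uncertainty.** Relative standard errors by the BHHH
(outer-product-of-scores) estimator: per-subject scores are central
finite differences of the importance-sampled marginal log-likelihood,
reusing the same draws on both sides of each perturbation. Bootstrap
percentile intervals are the heavier-duty alternative.

**EBEs and shrinkage.** Empirical Bayes estimates are per-subject
posterior modes of `η` (L-BFGS-B warm-started from the final chain
state); shrinkage is `100·(1 − SD(EBE)/ω)` per effect, NaN where
`ω = 0`.

## Synthetic cohorts

The generator emulates the pooled hypogonadal-male study this model was
built on; it is an emulation of printed summary statistics, not an
inference of the real joint distribution:

* seven study designs with the printed subject counts (146, 177, 131,
  143, 140, 85, 37) and sampling grids on the offsets {0, −2, …, −24} h
  from a reference dose time (08:00 by default; the dosing clock time is
  not part of the published summaries). The published per-offset study
  counts do not uniquely determine which study sampled which offset, so
  the default designs freeze one consistent assignment matching those
  counts and the pooled total of 4556 observations;
* ages truncated-normal (mean 50, SD 10, bounds 21–76 y); 42.8% of
  profiles in winter/spring; weight/BMI/height uniform within printed
  ranges; 77.2% non-Hispanic;
* simulation truth = the published final-model values: Base 239 ng/dL,
  Amplitude 32.1 ng/dL, t_max 9:22, t_min 14:02, semester +8.09%, age
  −2.40%/decade, Box–Cox −1.93, IIV CVs 10.6/19.0/50.3/25.1%, σ 13.8%.
  Within-block correlations default to zero because no correlation
  values are printed (the blocks are estimable and settable).

Random-effect vectors whose trough `Base_j − Amplitude_j` is
non-positive are rejected and redrawn (the model lives on positive
concentrations; without this the proportional-error redraw loop cannot
terminate); residual draws making an observation non-positive are also
redrawn. Both counts land in the dataset provenance.

Because ages are drawn with SD 10 rather than the ≈15 y effective spread
the real pooled cohort's reported precision implies, the simulated
information about the age slope is roughly half the real cohort's:
the expected age ΔOFV at n = 859 is ≈8 instead of ≈15.6. Semester
retention in the covariate search is robust (ΔOFV ≈ 23–50); age
retention is a coin-flip at the p < 0.001 backward threshold, and the
corresponding acceptance test documents this as the expected outcome of
these generating conditions rather than an estimation failure. Passing
calibration tests on these cohorts shows the machinery is self-consistent;
it does not certify behaviour on real data, whose age structure,
between-study heterogeneity and assay artifacts the generator does not
model.

## Evaluation

* **VPC**: `n_sim` full-dataset replicates at the fitted parameters on
  each subject's own design and covariates; quantile-based time bins
  (overridable edges); per-bin observed 5/50/95th percentiles against
  the median and 95% interval of the same percentiles across replicates,
  plus the fraction of observations below each pooled percentile
  surface.
* **NPDE**: per-subject decorrelation by the Cholesky root of the
  empirical simulation covariance (ridge-regularized with a warning if
  singular), rank-based probabilities clipped to
  [1/2K, 1 − 1/2K], mapped through the normal quantile; mean/SD with
  CIs and a Kolmogorov–Smirnov test against N(0,1).
* **Bootstrap**: subjects resampled with replacement to the original
  count (optionally stratified by study), each replicate refit with
  reduced SAEM settings; means and 2.5/97.5 percentile intervals over
  successful replicates, failures (exceptions or non-finite estimates)
  counted and excluded.

## Problem sizes in the shipped tests

Chosen for single-CPU runtimes: parameter recovery uses 400 subjects ×
dense 13-point schedule × 4 seeds (the reported tolerances are 3
across-seed SEs for fixed effects, 15%/10% relative for variance
components); model selection uses 200 subjects; the covariate search
runs 3 replicates at the full 859-subject pooled design; the bootstrap
check uses 12 replicates at 120 subjects against the original fit —
stability around the original-dataset estimates being what the bootstrap
qualifies; VPC/NPDE calibration run
at the generating truth on 200 subjects, which isolates the diagnostic
from estimation noise. The acceptance script averages three 400-subject
simulate-then-fit experiments.

## Known limitations

* The SAEM averaging phase leaves O(1/√K) wobble in weakly identified
  parameters (Box–Cox shape, covariate fractions at small n); the OFV of
  a converged fit carries a few points of estimation-and-Monte-Carlo
  noise, which the paired comparison machinery — not single OFV values —
  is designed to absorb.
* FOCE-style linearized diagnostics (CWRES) are deliberately absent;
  NPDE and prediction residuals cover that role.
* Additive or combined residual-error models and autocorrelated errors
  are out of scope; so is simulation of testosterone-replacement dosing
  (the model describes the pre-treatment baseline only).
* `t_max` carries high eta-shrinkage on every realistic design tested,
  so its EBE-based covariate screening is uninformative — hence the
  shrinkage < 30% gate and direct model testing for high-shrinkage
  parameters. For the same reason the likelihood estimate of the
  peak-time variance scatters widely across 400-subject cohorts and
  averages below the generating value; recovering it reliably takes the
  full pooled-cohort size.
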