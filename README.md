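# circamix

Population modelling of asymmetric circadian rhythms in hormone
concentrations, built around the baseline (pre-treatment) testosterone
rhythm of hypogonadal men.

Morning testosterone peaks around 9:20 and then falls to its nadir in the
early afternoon — much faster than the overnight recovery. A plain
cosinor, `Base + Amplitude·cos(2π(t − φ)/24)`, forces the decline and
recovery to take 12 h each. circamix implements the *stretched cosine*:
the phase is warped piecewise-linearly,

```
t24 = (t − t_max) mod 24
L1  = (t_min − t_max) mod 24,   L2 = 24 − L1
τ   = 12/L1 · t24              if t24 ≤ L1
    = 12 + 12/L2 · (t24 − L1)  otherwise
C(t) = Amplitude · cos(2π τ/24)
```

so the peak-to-nadir interval `L1` can differ from 12 h (≈ 4.7 h for
testosterone in hypogonadal men). On top of this structural model sits a
nonlinear mixed-effects (population) model:

* log-normal between-subject variability on `t_max`, `t_min`,
  `Amplitude` and `Base` (`P_j = P·e^{η_j}`), with two correlated 2×2
  blocks ({t_max, t_min} and {Amplitude, Base});
* a Box–Cox transform on the baseline random effect,
  `η* = ((e^η)^{θ₁} − 1)/θ₁`, giving the skewed baseline distribution
  seen in this population (θ₁ ≈ −1.9, negative skew);
* multiplicative covariate effects on `Base`: age (fraction per decade,
  centered on the median) and *semester* (winter/spring vs summer/fall);
* proportional residual error `y = f·(1 + ε)`, `ε ~ N(0, σ²)`.

Estimation is by SAEM (stochastic approximation EM) with a random-walk
Metropolis E-step; the objective function value (OFV = −2 log marginal
likelihood) is recomputed by adaptive importance sampling, model
comparison uses likelihood-ratio tests on OFV differences, and model
evaluation offers a visual predictive check, normalized prediction
distribution errors (NPDE) and a non-parametric (subject-resampling)
bootstrap. A two-stage covariate analysis (EBE screening, then
forward-inclusion p<0.005 / backward-elimination p<0.001) is included,
along with a synthetic-cohort generator that emulates the pooled study
structure this model was developed on (859 subjects, ~4556 samples on
seven sparse schedules).

## Worked example

```python
import circamix as cm

# 150 synthetic subjects on a dense 13-point schedule, simulated from the
# published final-model values (Base 239 ng/dL, Amplitude 32.1 ng/dL,
# peak 9:22, nadir 14:02, Box-Cox -1.93, age -2.4%/10 y, winter/spring +8.1%)
ds = cm.dense_cohort(150, seed=7)

fit = cm.CircadianMixedModel(ds).fit(settings=cm.SaemSettings.fast(), seed=8)
print(fit.summary())
```

```
Circadian mixed-effects model fit
  structural model : stretched_cosine
  subjects / observations : 150 / 1950
  OFV : 20015.66 (MC SE 5.20)
  estimated parameters : 14
  converged : True

  Parameter                       Estimate    RSE%
  t_max (clock time)                 9.569       -   [9:34]
  t_min (clock time)                 14.05       -   [14:03]
  amplitude (ng/dL)                   35.1       -
  base (ng/dL)                         237       -
  theta_age (% on base)             -0.131       -
  theta_semester1 (% on base)         9.49       -
  Box-Cox shape on base              -2.49       -
  Interindividual variability (CV%)
      eta_t_max                        9.6       -
      eta_t_min                         20       -
      eta_amplitude                     45       -
      eta_base                        26.1       -
  Residual variability (CV%)
      sigma_proportional                14       -
  eta-shrinkage: t_max 60%, t_min 17%, amplitude 23%, base 6%
```

The recovered typical values sit close to the generating ones (base
237 vs 239 ng/dL, amplitude 35.1 vs 32.1, peak 9:34 vs 9:22, nadir 14:03
vs 14:02, residual CV 14.0% vs 13.8%); at 150 subjects the covariate
fractions and the Box-Cox shape are still noisy, which is exactly what
their large fitted spread says. Diagnostics hang off the fit:

```python
rep = cm.vpc(fit, n_sim=200, seed=9)
print(rep.fraction_below)   # {5.0: 0.055, 50.0: 0.505, 95.0: 0.950}
nd = cm.npde(fit, n_sim=500, seed=10)
print(nd.mean, nd.sd)       # -0.008 1.018  (≈ N(0,1) under a correct model)
```

Fractions of observations below the predicted 5th/50th/95th percentile
curves near 5/50/95% and NPDE moments near (0, 1) say the fitted model
reproduces its own data-generating process.

There is also a CLI mirroring the library
(`circamix simulate|fit|vpc|npde|bootstrap|covsearch|run`); `run`
executes a multi-stage YAML pipeline with one global seed.

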