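# tlechen

Topp-Leone exponentiated Chen (TLEC) lifetime distributions: numerically
stable distribution kernels, maximum-likelihood fitting with Wald intervals,
Monte-Carlo evaluation of the estimator, and model comparison on bundled
COVID-19 case-count data.

## The model

The Chen distribution is a two-parameter lifetime law with CDF

    F_C(x; λ, β) = 1 − exp(λ(1 − e^(x^β))),    x > 0, λ > 0, β > 0,

popular in reliability work because its hazard can be bathtub-shaped
(β < 1) or increasing (β ≥ 1).  Raising the CDF to a power b > 0 gives the
exponentiated Chen (EC) family, and pushing that through the Topp-Leone
generator G ↦ [1 − (1 − G)²]^α yields the four-parameter TLEC law

    F(x; α, λ, β, b) = [1 − (1 − F_C(x)^b)²]^α,

whose extra shape parameters α (Topp-Leone) and b (exponentiation) buy a
wide range of hazard shapes — increasing, decreasing and bathtub — and both
left- and right-skewed densities.  Setting b = 1 gives the Topp-Leone Chen
(TLC) sub-family.  The quantile function is available in closed form, so
random variates come from inverse-transform sampling.

Fitting is by maximum likelihood: Nelder-Mead over log-transformed
parameters from a deterministic cascade of warm starts (Chen → EC/TLC →
TLEC) plus seeded random restarts, observed-information standard errors, and
Wald intervals.  Model comparison uses AIC, CAIC, BIC and HQIC.

A caution that the package makes explicit: the TLEC likelihood is weakly
identified — β and b trade off along a nearly flat ridge, and for data far
from the origin the scale λ collapses towards zero.  Fits flag boundary
solutions and the methods note (`docs/methods.md`) describes the
consequences for estimation and simulation.

## Worked example

Fit the four bundled models to the 65 daily infected-case counts
(Saudi Arabia, 1 January – 6 March 2022) and rank them:

```python
from tlechen import load_dataset, compare_models, fit_mle

data = load_dataset("infected")
fit = fit_mle(data.values, "tlec", n_restarts=20, seed=0)
print(fit.summary())
```

```
TLEC maximum-likelihood fit
==========================================================
n_obs     65    log-lik    -570.4997    -2 log-lik  1140.9994
AIC   1148.999  CAIC   1161.697  BIC   1157.697  HQIC   1152.431
converged: True   restarts used: 23
----------------------------------------------------------
   param     estimate    std err     [0.95          ]  bdry
   alpha    0.0280503     0.0746    -0.1182     0.1743
     lam        1e-08  1.292e-07 -2.432e-07  2.632e-07     *
    beta     0.339647    0.07834     0.1861     0.4932
       b      8.27756      17.54     -26.09      42.65
```

The `*` marks the scale parameter pinned at the positivity floor: on counts
in the thousands the likelihood pushes λ towards zero (see the methods
note).  The comparison table (each model charged its own parameter count):

```python
df = compare_models(data, ["tlec", "ec", "chen", "tlc"], seed=0, n_restarts=20)
print(df[["model_label", "minus2loglik", "aic", "bic", "k", "rank"]])
```

```
model_label  minus2loglik         aic         bic  k  rank
         EC   1141.980058 1147.980058 1154.503220  3     1
        TLC   1142.081664 1148.081664 1154.604826  3     2
       TLEC   1140.999361 1148.999361 1157.696910  4     3
       CHEN   1148.644224 1152.644224 1156.992999  2     4
```

The TLEC attains the best log-likelihood (−2 log L = 1141.0); once AIC/BIC
charge it for its fourth parameter, the three-parameter EC edges it out.
`compare_models(..., k_policy="uniform")` instead penalises every model as
if it had the largest parameter count in the comparison, the convention of
the original published table for these data, under which the ranking
reduces to the −2 log L ordering and the TLEC places first.

A Monte-Carlo study of the estimator (bias, MSE, interval length, coverage):

```python
from tlechen import TlecParams, SimulationConfig, run_mc_study, coverage_table

cfg = SimulationConfig(TlecParams(0.6, 0.9, 0.5, 0.3),
                       sample_sizes=(50, 300), reps=1000, seed=2024)
study = run_mc_study(cfg)
print(coverage_table(study))
```

There is also a CLI: `tlechen sample|fit|compare|simulate|props --help`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
refits the TLEC, EC, Chen and TLC models to the two bundled datasets from
scratch (multi-start MLE), reports their −2 log-likelihoods and the fitted
TLEC shape parameters, and regenerates the Case-1 Monte-Carlo study
(1000 replicates at sample size 300) to report the mean estimate of α and
the empirical coverage of its 95% Wald interval.  It runs in about a minute
on one CPU.
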