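# mprsurv

Survival analysis of a population-based lung-cancer cohort (855 incident
cases, ~79% dead within the 20-month study window) in which treatment effects
are *not* proportional-hazards: the benefit of therapy wanes with time since
diagnosis. The package implements the full analysis pipeline over such a
cohort — nonparametric description, a non-PH parametric survival model, a
treatment-allocation model, and the screening-table reconciliation of the
two — together with a synthetic-cohort generator that reproduces the cohort's
published statistical structure, so every stage runs and is testable without
the (undeposited) study data.

It is intended for biostatisticians and epidemiologists studying treatment
effects in observational survival data where allocation to therapy is itself
driven by prognosis.

## The models

**Weibull multi-parameter regression (MPR).** The hazard is
λ(t) = λγt^(γ−1), with *both* Weibull parameters given their own linear
predictor through log links:

    λ_i = exp(x_i'β)   (scale)        γ_i = exp(z_i'α)   (shape)

Covariates in the shape predictor make hazard ratios time-dependent; an
intercept-only shape recovers the standard Weibull proportional-hazards
model, so the PH assumption becomes a testable sub-model (compared by AIC).
The right-censored log-likelihood

    ℓ(β,α) = Σ_i [ δ_i (x_i'β + z_i'α + (e^{z_i'α} − 1) log t_i) − e^{x_i'β} t_i^{e^{z_i'α}} ]

is maximised jointly by BFGS with the analytic gradient plus a damped Newton
polish; standard errors come from the inverse observed information. Forward
stepwise selection adds whole factors to the scale *or* the shape by AIC.
Case-mix-adjusted survival tracks evaluate the fitted model for a subject on
a given treatment who is average (dummy-column means) on all other factors.

**Treatment-allocation model.** Pr(treated) = exp(x'β)/(1+exp(x'β)), a
logistic regression of curative-intent treatment on the same covariate pool,
fitted by ML (statsmodels) with AIC forward selection. Its fitted
probabilities feed an epidemiological **screening table** at a 0.5 cut-off:
cell a (concordantly untreated), b (false positives — untreated subjects the
model would treat), c (concordantly treated), d (false negatives), with
sensitivity c/(c+d) and specificity a/(a+b). Survival is then stratified by
screening cell and by quartile of allocation probability.

**Kaplan–Meier / log-rank.** Product-limit curves with Greenwood variance and
complementary log-log confidence limits, and the k-group log-rank test, are
implemented directly (lifelines serves as an independent cross-check in the
test suite).

## Worked example

```sh
mprsurv simulate --mode full --n 855 --seed 5 --out-dir scratch
mprsurv analyze scratch/cohort_full_n855_seed5.csv --out-dir scratch/out
```

prints

```
wrote scratch/cohort_full_n855_seed5.csv (855 subjects, 687 deaths)
wrote scratch/out/report.json
overall: median 5.3 months, 1-year survival 23.5%
screening: sensitivity 72.3%, specificity 68.4%
```

Half of this simulated cohort is dead by 5.3 months and under a quarter survive the
first year, matching the grim prognosis the generator encodes. The screening
numbers say the fitted allocation model and the simulated "clinician"
disagree on roughly a quarter of subjects in each direction. The report JSON
additionally contains the treatment-only MPR fit and its PH comparison (the
non-PH model wins by tens of AIC units on cohorts generated with real shape
effects), the stepwise multi-factor solution, and per-cell/per-quartile
survival summaries.

The numbered drivers under `analysis/` run the same stages as a narrated
sequence — `01_simulate.py` through `05_screening.py` — writing their tables
under `results/`.

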