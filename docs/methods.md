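# Methods

## The cohort and what the generator emulates

The analysis concerns a population-based cohort of 855 incident primary
lung-cancer cases accrued over one year and followed to an administrative
study end, giving each subject a maximum possible follow-up of 20 months
(one summary source quotes 21 months; the study-end mechanism implies 20,
which is what the generator uses). Time is measured in months from
diagnosis; the outcome is all-cause death. Because the subject-level data
are not deposited, every analysis here runs on synthetic cohorts that
reproduce the cohort's *published* statistical structure:

- **Covariates** are drawn independently from their published marginal
  counts (performance status 78/278/286/213; age bands 32/89/311/299/124;
  cell type 247/121/108/379; metastases 188/428/239; albumen 458/315/82).
  The joint distribution is unpublished, so marginals are all the generator
  can — and needs to — match: conditional-model parameter recovery only
  requires design variation, not the true covariance. Margins for sex,
  sodium and smoking were never printed; the defaults (male 0.67; sodium
  ≥136 / <136 / unknown 0.68/0.22/0.10; smoking never/current/ex/unknown
  0.07/0.45/0.40/0.08) are plausible early-1990s lung-cancer values, fixed
  once.
- **Treatment** is either multinomial at the published group sizes
  (79 surgery, 45 chemotherapy, 256 radiotherapy, 34 combined,
  441 palliative; `treatment_only` mode) or allocated by the logistic model
  below (`full` mode), with the specific therapy among treated subjects
  drawn from the (79, 45, 256, 34)/414 split independently of covariates —
  the allocation model is binary, so sub-allocation is deliberately
  unmodelled. "Treated" means any non-palliative category; the published
  margins count all radiotherapy as treated even though most of it was
  palliative in intent, and the generator follows the margins.
- **Survival** is drawn exactly from the Weibull MPR hazard by inverse
  transform, T = (−log U / λ)^{1/γ}, at the published coefficient sets.
- **Censoring** is purely administrative: entry uniform on [0, 12) months,
  censor time 20 − entry, observed time min(T, C), event T ≤ C. No loss to
  follow-up is simulated because none is described. Under the default
  treatment-only truth this yields ≈ 80% deaths, close to the published
  78.7%.

What passing tests therefore show is that the *estimators* are correct and
recover known truth under the cohort's design; they cannot show robustness
to covariate dependence, non-administrative dropout, or misrecorded times,
none of which the generator produces.

### The allocation intercept

The published allocation coefficients put the best-prognosis reference
subject (normal performance status, under 40, squamous, no metastases,
albumen ≥ 3.5) at the *highest* treatment probability, with every worse
level lowering it. For the model to reproduce the treated margin 414/855,
a 0.5 cut-off that splits the screening table nearly symmetrically, and a
top probability quartile at ≥ 0.75, the intercept must be +3.0315: with a
negative intercept of the same magnitude the mean allocation probability
would be below 0.01 and the reference subject near 0.05. The generator
therefore uses +3.0315; this is a deliberate sign correction of an
apparently misprinted summary value, argued purely from internal
consistency (verified numerically against the margins).

### Performance-status coding

The survival coefficient set was originally reported on a five-grade
performance-status scale, while the allocation model and the subject schema
use four levels (normal / light work / no work / ≥50% waking time bed- or
chair-bound). The two most severe grades collapse into the fourth level;
the generator's survival default keeps the bed/chair-bound scale
coefficient (1.624) for it, and the residual fifth dummy (1.077) has no
counterpart in the four-level coding and is unused.

## Model fitting

**Weibull MPR.** The right-censored log-likelihood (hazard λγt^{γ−1},
λ = e^{x'β}, γ = e^{z'α}) is maximised jointly over (β, α), which the log
links leave unconstrained. Numerical choices:

- Start at the exponential submodel: scale intercept log(Σδ/Σt), all other
  coefficients 0 — consistent under the null and cheap. Stepwise moves warm
  start from the incumbent fit.
- BFGS with the analytic gradient (target gradient-norm 1e-8), followed by
  a damped Newton polish on the numerically differentiated observed
  information, because BFGS line searches can stall on precision loss a few
  orders short of the target. A fit is flagged `converged` only when the
  final sup-norm of the gradient is below 1e-5.
- Inside the optimizer the shape linear predictor is clipped at 20 and the
  log cumulative hazard at 400 so that wild line-search trial points return
  enormous-but-finite objective values instead of overflowing; the clip is
  far outside any plausible optimum and cannot bind at a flagged-converged
  solution. The public likelihood function does not clip — it raises on
  non-finite predictors.
- Standard errors are square roots of the diagonal of the inverse observed
  information (central differences of the analytic gradient, step
  1e-5·max(1, |θ|)). A non-positive-definite information marks the fit
  non-converged rather than silently producing NaNs.
- Small treatment arms can create genuinely unbounded likelihood ridges
  (the Weibull analogue of separation: a handful of tightly clustered event
  times pushed toward a degenerate distribution). Such fits are flagged,
  and forward selection skips flagged candidates instead of selecting a
  diverged model.

**Forward selection** starts from intercept-only scale and shape and, at
each step, tries adding every remaining factor (all its dummies at once) to
either component, accepting the single move with the largest AIC decrease
and stopping when none decreases it. AIC is the entry criterion for both
the survival and allocation models — the original analyses used software
specific entry rules (score tests in the allocation model's case), so the
selected sets may differ from the published ones in borderline cases; on
default synthetic cohorts the selection reproduces the published structure
(treatment, metastases and albumen in both components; performance status,
cell type and sodium scale-only; smoking shape-only; age and sex rejected).

**Reference levels** are fixed to the published ones: palliative
(treatment), normal (performance status), squamous (cell), absent
(metastases), ≥3.5 (albumen), ≥136 (sodium), never (smoking), <40 (age),
male (sex). Reference coefficients are identically zero, and the reported
significance convention is |z| = |mle/s.e.| ≥ 2. Age is assumed to enter
the survival selection as the same five-band factor used by the allocation
model.

**Logistic allocation model.** Fitting is delegated to statsmodels' Newton
ML (`Logit`); this module owns the factor coding, AIC forward selection,
prediction and the screening table. Perfect separation is flagged on the
returned fit, never silent.

**Kaplan–Meier / log-rank** are implemented directly (the independent
reference implementation, lifelines, is used only as a test oracle).
Deaths precede censorings at tied times; the confidence band is
complementary log-log (Kalbfleisch–Prentice), which stays inside [0, 1]
and is undefined-degenerate (collapsed to the estimate) where S is 0 or 1;
the median is the earliest event time with S ≤ 0.5, undefined if never
reached. The k-group log-rank statistic uses the hypergeometric variance
with a pseudoinverse quadratic form over k − 1 groups.

**Screening table.** Probability exactly at the cut-off classifies as
"treat" (deterministic tie rule). Quartiles are assigned by stable rank
(ties broken by input order) with the remainder allocated to the upper
groups, so n = 855 splits 213/214/214/214 with 214 subjects on the top
track.

## Degenerate inputs

Nonpositive survival times, empty cohorts, single-class outcomes,
single-group log-rank calls, factor levels with no subjects, unknown factor
levels, and counts/proportions that fail to normalise all raise validation
errors; an all-censored sample is a valid KM input (S ≡ 1, median
undefined), and an empty screening cell drops its curve with a warning
rather than failing the partition.

## Problem sizes

Replicated experiments (parameter recovery for both models, AIC-direction
checks) use 200 replicates of the study size n = 855, which puts
Monte-Carlo error on mean recovered coefficients near 0.01–0.04 — small
against the published standard errors (0.07–0.9). The bias-shrinkage check
contrasts n = 855 with n = 3420 over 30 replicates. Property tests use
cohorts of 12–3000 as appropriate to the property.

## Known limitations

- Independent covariate sampling understates real case-mix confounding;
  adjusted-track contrasts on synthetic data are therefore weaker and
  noisier than on the real cohort, and single replicates can move in either
  direction.
- Data-dependent published results (overall median 4.7 months, one-year
  survival 24.5%, the 43-unit AIC gap, the exact selected model) are not
  reproducible from summary statistics; the pipeline reproduces their
  qualitative structure and the desk-scale arithmetic exactly, and the
  synthetic analogues land nearby (median ≈ 5.1, one-year ≈ 23%, AIC gap
  ≈ 40 on average).
- Only all-cause mortality is modelled; cause-specific mortality was
  reported to be nearly identical in this cohort.
- No stratified/weighted survival-curve tests, competing risks, Cox
  partial-likelihood fitting, time-varying covariates, frailty, or
  non-Weibull distributions; no ROC-style cut-off optimisation for the
  screening table.
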