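# Methods

## The model

Daily dose-taking from an electronically monitored (MEMS-style) once-daily
regimen is reduced to a binary state per calendar day: 1 if the container was
opened at least once that day, 0 otherwise (multiple openings collapse to
one).  The sequence of states for subject *i* is modelled as a first-order
two-state Markov chain with transition probabilities

    logit P01,it = θ1 + x'_it β01 + η1,i      (re-initiation after a miss)
    logit P10,it = θ2 + x'_it β10 + η2,i      (discontinuation after a dose)

and P00 = 1 − P01, P11 = 1 − P10.  Covariates enter additively on the logit
scale; exp(β) is the odds ratio of the corresponding transition.  The random
effects η are normal with mean zero and variance ω²; the previous state of
each subject's first observed day is fixed at 1 (dose taken), a choice that
matters little when overall adherence is high and that is overridable.

The comparator is the Bernoulli ("coin flip") model logit P1 = θ1 + η_i,
which ignores state history.  The difference in −2·log-likelihood between the
two fits, and the behaviour of replicate simulations from each, are the two
model-comparison diagnostics the package reports.

**Random-effect structure.** The logit equations are ambiguous between one
shared η entering both logits and two independent effects.  The default is
two independent effects (one per logit, variances ω1², ω2²), which is the
standard structure in published mixed-effects Markov adherence models and
approximately nests the shared case; `random_effects="shared"` and `"none"`
are available.  With independent effects the marginal likelihood factorizes
over prev=0 and prev=1 records, so the Markov fit reduces to two independent
mixed-effects logistic problems — the fitter exploits this.

## Estimation

The marginal likelihood integrates each subject's conditional chain
likelihood over the random-effect distribution.  The default approximation
is the Laplace method: the posterior mode of each η is found by damped
Newton iteration (the per-subject objective is strictly concave; steps are
clipped to ±4 logits), and the integral is approximated from the mode and
the curvature there.  Adaptive Gauss–Hermite quadrature (`method="agq"`,
configurable nodes) and non-adaptive Gauss–Hermite (`"ghq"`) are implemented
as accuracy oracles; on small cohorts the Laplace value agrees with 64-node
adaptive quadrature to well under 0.5%.

The outer maximization runs L-BFGS-B on (θ, β, log ω²), starting from the
empirical logit of the pooled transition frequency, β = 0 and ω² = 0.1.
All likelihood computation is in log space; probabilities are clipped to
[1e−12, 1−1e−12] inside logarithms only.  Standard errors come from a
central finite-difference Hessian of the −2·log-likelihood at the optimum
(relative step 1e−4 on the working scale); 95% Wald intervals use the fixed
multiplier 1.96 on the log-OR scale.  With ω² = 0 and no covariates the fit
reproduces the closed-form transition-frequency MLE, which the tests assert.

## Covariate screening and model selection

Before fitting, covariates can be screened for sparse transition support: a
covariate is dropped when, within any one of its categories, any of the four
transition types [01],[11],[10],[00] accounts for strictly less than 5% of
that category's transitions (exactly 5% is retained; a pooled-across-
categories variant is available, within-category is the default because
sparse *sub-categories* are what make such effects unstable).

The full model assigns every retained covariate to both logits.  Backward
elimination then iterates: fit, compute the OR-scale 95% intervals, drop
every effect whose interval contains 1, refit, until nothing drops.
Elimination is per effect (covariate × logit), so a covariate can survive on
one logit only; each level of a multi-level covariate is dropped
individually.  Simultaneous removal within an iteration is the default,
one-at-a-time removal (weakest effect first) is an option.  Non-convergence
at any step halts the procedure with the history recorded.

## Non-therapeutic time and predictive checks

With a 24 h assumed duration of drug action, one isolated missed dose leaves
no unprotected day.  NTT is therefore computed per maximal run of k ≥ 2
consecutive misses as k − 1 days (the "capped" rule).  An alternative
reading counts all k days of such a run; it is available as `rule="full"`,
but the capped rule is the default because it follows directly from the
24 h duration-of-action argument.

Model adequacy is judged by simulation from each subject's individual
transition matrix — transition probabilities evaluated at the subject's
posterior-mode (empirical Bayes) random effects and per-day covariates:

- **NTT diagnostic**: 100 replicate chains per subject at the observed
  series length; the mean replicate NTT is paired with the observed NTT and
  the Pearson correlation over subjects reported.
- **Transition-count check**: five whole-cohort replicates; the four
  transition counts per replicate are tabulated next to the observed counts.
  Because series lengths are fixed, every replicate's total equals the
  observed total.  A fit that ignores persistence (the Bernoulli comparator)
  overpredicts the [10] and [01] switch counts several-fold on persistent
  data, which is the signature the check is designed to expose.

## Synthetic cohorts

The generator emulates a PrEP demonstration cohort of HIV serodiscordant
couples.  Defaults: 920 subjects, 360 daily states, independent covariate
draws at the study's marginal prevalences (male 65% — coded as female 35% —
age over 25 80%, sex-risk no-sex/100%-condom/<100%-condom 4/34/62% with
no-sex as reference, partner on ART ≥ 6 months 52%, wants the relationship
to succeed 88%, follow-up beyond 6 months 57%, problem alcohol use 20%),
covariate effects at the published odds ratios (the only printed effect
sizes), and ω² = 0.5 per logit.  Intercepts are solved so that a typical
subject (prevalence-mean covariates, η = 0) has P01 ≈ 0.27 and P10 ≈ 0.10,
which reproduces the observed dominance of [11] transitions (≈ 65%) and a
stationary adherent fraction of ≈ 0.73.  Each dose-taking day emits one
opening timestamp jittered uniformly between 06:00 and 22:00, exercising
the timestamp parser without affecting the daily reduction.

What the generator does **not** emulate: curiosity/false-positive openings,
device loss and missing-visit gaps, couple-level correlation between
covariates (draws are independent; only marginal prevalences are known),
within-subject changes in behavioural covariates between visits, and dose
timing effects within a day.  Passing recovery tests therefore demonstrate
that the estimation machinery is correct under the model's own assumptions,
not that the model is robust to these real-data features.  The optional
time-varying extension switches the follow-up indicator at day 183 for all
subjects and the partner-ART indicator at per-subject days, re-simulating
the chains with day-specific probabilities.

Scale choices in the test suite: oracle comparisons run at 5–10 subjects ×
20–30 days, recovery and selection checks at 150–300 subjects × 100–150
days with 5–10 seeded replicates, and one full-scale (920 × 360) recovery
run; these sizes make each check's Monte-Carlo error small relative to what
it asserts.  The acceptance script repeats the full-scale simulate-then-fit
experiment on eight derived sub-seeds and reports per-effect mean odds
ratios, which tightens the Monte-Carlo precision of an unbiased estimator
without altering any generating condition.

## Pharmacokinetic link

Adherence chains become dosing histories (one dose per state-1 day at a
fixed clock time) and plasma concentrations are computed by superposition of
the closed-form single-dose solution of a linear one- or two-compartment
model with first-order absorption (ka = ke handled by the analytic limit
branch).  Units: dose in mg, clearances L/h, volumes L, concentrations
ng/mL, with bioavailability folded into the apparent parameters and no
prodrug conversion modelled.  Threshold metrics (fraction of time below,
longest continuous time below, first crossing times) use piecewise-linear
interval accounting with a strict "below" convention; the default threshold
is 40 ng/mL and the default dose 300 mg.  The shipped TFV-like parameter set
(ka 1.0 h⁻¹, CL/F 42 L/h, Vc/F 380 L, Q 180 L/h, Vp/F 560 L) is
illustrative only — it is not a fitted population model, and the CLI's
`--strict` mode refuses to run with it.

## Known limitations

- First-order chains only; no higher-order memory, inter-occasion
  variability, or covariate effects on ω².
- Wald intervals and the Laplace approximation can be optimistic for very
  short series or near-boundary ω²; the quadrature oracle is the check.
- The elimination procedure inherits the usual caveats of CI-based backward
  selection (no multiplicity control, order effects in sequential mode).
- The PK layer is illustrative of the adherence → exposure cascade; it makes
  no efficacy claims and does not model intracellular metabolites.
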