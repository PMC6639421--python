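# prepmarkov

Mixed-effects two-state Markov modelling of daily PrEP adherence from
electronic (MEMS) pill-container monitoring.

## The problem

Electronic adherence monitoring timestamps every pill-container opening and
is the only adherence measure that yields a day-by-day record of dose-taking
behaviour.  Summary measures (percent adherence) discard the *pattern* of
that record, yet patterns are what matter clinically for pre-exposure
prophylaxis (PrEP): consecutive missed doses leave a person unprotected in a
way scattered single misses do not, and ignoring the serial dependence of
daily outcomes inflates type-I error in covariate selection.  This package
is for biostatisticians and pharmacometricians analysing such data — for
instance from PrEP programmes in HIV serodiscordant couples — who want a
mechanistic, simulation-capable model of adherence dynamics rather than a
marginal regression.

## The model

Each day is a binary state, dose-taking (1) or dose-missing (0), and the
sequence is a first-order Markov chain.  For subject *i* on day *t*:

    logit P01,it = θ1 + x'_it β01 + η1,i        P00 = 1 − P01
    logit P10,it = θ2 + x'_it β10 + η2,i        P11 = 1 − P10

where P01 is the probability of re-initiating after a missed dose, P10 the
probability of discontinuing after a taken dose, x a covariate vector acting
additively on the logits, and η ~ N(0, ω²) subject-level random effects (one
independent effect per logit by default).  exp(β) is an odds ratio: OR < 1
on P10 means higher persistence, OR > 1 on P01 means readier re-initiation.
The marginal likelihood is maximized with a Laplace approximation (adaptive
Gauss–Hermite quadrature available as an oracle), a Bernoulli "coin flip"
model serves as the no-memory comparator, covariates are selected by
backward elimination on 95% OR confidence intervals, and the fit is checked
by simulating non-therapeutic time (NTT — days unprotected due to
consecutive misses) and replicate transition counts from each subject's
empirical-Bayes transition matrix.  A PK layer turns simulated adherence
chains into plasma concentration profiles by linear-compartment
superposition.  A synthetic cohort generator with the demographic mix and
published effect sizes of a PrEP demonstration cohort makes the entire
pipeline testable without study data.  See `docs/methods.md` for details.

## Worked example

```python
import numpy as np
import prepmarkov as pm

spec = pm.CohortSpec(n_subjects=300, n_days=180)     # scaled-down cohort
cohort = pm.generate_cohort(spec, seed=42)
dataset = cohort.to_dataset()

result = pm.fit(dataset)                   # Markov mixed-effects, Laplace
bernoulli = pm.fit_bernoulli(dataset)      # no-memory comparator
print(f"-2 log L: Markov {result.neg2ll:.1f}  Bernoulli {bernoulli.neg2ll:.1f}  "
      f"drop {bernoulli.neg2ll - result.neg2ll:.1f}")

table = pm.effects_frame(pm.odds_ratios(result))
print(table[["effect", "parameter", "OR", "ci_low", "ci_high"]]
      .round(3).to_string(index=False))

pairs, corr = pm.ntt_diagnostic(result, dataset, rng=np.random.default_rng(0))
print(f"observed-vs-predicted NTT correlation: {corr:.3f}")
```

prints

```
-2 log L: Markov 41925.7  Bernoulli 58446.9  drop 16521.2
            effect parameter    OR  ci_low  ci_high
       age_over_25       P01 1.018   0.814    1.272
            female       P01 1.075   0.886    1.305
    partner_art_6m       P01 0.830   0.694    0.994
wants_relationship       P01 1.469   1.128    1.913
       followup_6m       P01 0.881   0.734    1.057
   problem_alcohol       P01 0.655   0.515    0.832
        condom_100       P01 1.027   0.675    1.563
      condom_lt100       P01 1.154   0.768    1.734
       age_over_25       P10 0.648   0.514    0.817
            female       P10 0.730   0.599    0.890
    partner_art_6m       P10 1.259   1.046    1.515
wants_relationship       P10 0.880   0.669    1.157
       followup_6m       P10 1.277   1.059    1.540
   problem_alcohol       P10 1.142   0.892    1.464
        condom_100       P10 1.109   0.717    1.717
      condom_lt100       P10 0.758   0.496    1.157
observed-vs-predicted NTT correlation: 0.993
```

The ~16,500-point objective drop shows how strongly daily states depend on
the previous day's state; the OR table recovers the generating effect sizes
(e.g. age on P10 generated at 0.61, estimated 0.648 with CI 0.514–0.817 at
this reduced cohort size); and the NTT correlation near 1 says the fitted
individual transition matrices reproduce each subject's burden of
consecutive missed days.

The same pipeline runs from the shell over CSV inputs
(`prepmarkov simulate | fit | select | ntt | pk`, each driven by a YAML
config with a global seed; `prepmarkov fit --compare-bernoulli` adds the
model comparison).

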