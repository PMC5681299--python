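# anticipation

Regression models for **genetic anticipation** — progressively earlier
disease onset in successive generations — in **Lynch syndrome** families,
the autosomal-dominant cancer-predisposition syndrome caused by germline
mutations in the mismatch-repair genes *MLH1*, *MSH2*, *MSH6* and *PMS2*
(or *EPCAM* deletions silencing *MSH2*).

The package is aimed at statistical genetics and cancer-registry analysts:
it takes a flat table of at-risk mutation carriers (one row per carrier,
with family membership, gene, sex, generation or parent links, and age at
first Lynch-associated diagnosis or at last follow-up) and answers "do
later generations get diagnosed earlier?" with two complementary
likelihood-based models that use the partial follow-up of carriers who have
not (yet) been diagnosed, instead of discarding them as affected-pair
methods do.

## The two models

**NREM** — a censored normal random-effects model of onset age.  For
carrier *j* of family *i*,

    T_ij = mu_i + gamma * Z_ij + beta' X_ij + eps_ij,

where `mu_i ~ N(E(mu), Var(mu))` is a family-specific intercept (a typical
onset age for the family), `Z_ij` is the carrier's generation coded from
the oldest observed generation of the family (oldest = 0), `X_ij` holds
sex and gene indicators (*MLH1* is the reference category), and
`eps_ij ~ N(0, sigma^2)`.  `gamma` is the mean change in onset age per
generation: **anticipation is indicated by `gamma < 0`**.  Carriers still
diagnosis-free at last follow-up contribute the normal survivor function
`P(T > C)`; the family intercept is integrated out with adaptive
Gauss–Hermite quadrature and the marginal likelihood maximised directly.

**COX-R** — a mixed-effects proportional-hazards model,

    lambda(t | Z_ij, X_ij) = lambda_0(t) exp(mu~_i + gamma~ Z_ij + beta~' X_ij),

with a nonparametric baseline hazard `lambda_0` and a Gaussian family-level
random effect `mu~_i` (a log-normal frailty): families' baseline hazards
are proportional rather than identical.  `gamma~` is the generational
log-hazard ratio, so **anticipation is indicated by `gamma~ > 0`**, with
`exp(gamma~)` the multiplicative increase in diagnosis rate per
generation.  Fitting maximises the Laplace-approximated partial likelihood
integrated over the frailties (penalized Newton inner updates, bounded 1-D
outer search over the frailty variance); ties use the Efron approximation.

Both models have a gene–generation interaction variant in which the scalar
`Z` is replaced by `Z * (1[MLH1], 1[MSH2], 1[MSH6], 1[PMS2])`, giving one
anticipation effect per gene.  The package also provides the cohort
assembly rules (EPCAM→MSH2 grouping, dual-mutation reassignment, the
exclusion cascade, generation coding), Kaplan–Meier summaries (median onset
with band-inversion CIs, reverse-KM median follow-up), and a seeded
generator of Lynch-like multi-generation cohorts for validation.

## Worked example

```python
from anticipation import generate_cohort, build_design, fit_nrem, fit_coxr
from anticipation.simulate import CohortConfig

cfg = CohortConfig(seed=1)          # 239 Lynch-like families
carriers, families = generate_cohort(cfg)
design = build_design(carriers)

nrem = fit_nrem(carriers, design)
coxr = fit_coxr(carriers, design)

g, (glo, ghi) = nrem.estimates["gamma"], nrem.ci95["gamma"]
print(f"NREM  gamma = {g:.2f} years/generation  (95% CI {glo:.2f}, {ghi:.2f}; "
      f"p = {nrem.wald_p['gamma']:.4f})")
gt, (tlo, thi) = coxr.estimates["gamma_tilde"], coxr.ci95["gamma_tilde"]
print(f"COX-R gamma~ = {gt:.3f}  (95% CI {tlo:.3f}, {thi:.3f}; "
      f"hazard ratio {coxr.hazard_ratios['gamma_tilde']:.2f})")
print(f"family effects: Var(mu) = {nrem.estimates['var_mu']:.2f} years^2, "
      f"Var(mu~) = {coxr.params.var_frailty:.3f}")
```

prints

```
NREM  gamma = -2.30 years/generation  (95% CI -3.14, -1.45; p = 0.0000)
COX-R gamma~ = 0.203  (95% CI 0.122, 0.284; hazard ratio 1.23)
family effects: Var(mu) = 6.96 years^2, Var(mu~) = 0.083
```

The simulated cohort was drawn with a true `gamma` of −2.10 years per
generation and a frailty variance of 0.101, so both models point the same
way: onset gets roughly two years earlier per generation (NREM), or
equivalently each generation is diagnosed at about a 1.2-fold higher rate
(COX-R), with modest between-family heterogeneity.

The same analysis runs from the shell:

```sh
anticipation simulate --out sim/ --seed 1
anticipation summarize --input sim/cohort.csv
anticipation fit --input sim/cohort.csv --models nrem,coxr \
    --interactions both --out results/ --seed 1
```

`fit` writes a descriptive summary table, an anticipation-effects table
(both models, with and without interactions), a full parameter table with
standard errors, 95% Wald CIs and p-values, Kaplan–Meier curves per gene,
and the exclusion-cascade log.

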