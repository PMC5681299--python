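# Methods

## Cohort model and assembly rules

A cohort is a list of at-risk mutation carriers grouped into families.
Assembly applies, in order:

1. **Gene grouping.** *EPCAM*-deletion families are analysed with the
   *MSH2* families (the deletion silences *MSH2* in *EPCAM*-expressing
   tissue); families carrying both *MLH1* and *PMS2* mutations are analysed
   as *PMS2*.  The analysis categories are MLH1, MSH2, MSH6, PMS2, with
   MLH1 the reference in all designs.
2. **Generation coding.** Each carrier's generation covariate `Z` is its
   depth below the oldest observed generation of its family (oldest = 0).
   When parent links are available, depth is the number of
   carrier-to-carrier parent steps from the family's founder carriers
   (carriers without a carrier parent in the family); with two carrier
   parents the deeper one counts.  An explicitly supplied depth wins over
   the link-derived value, with a logged warning on disagreement, and
   family depths are normalised to minimum 0.  Carriers with neither links
   nor explicit depth are treated as founders; cyclic links are an error.
3. **Exclusion cascade**, in fixed order so the log can be audited against
   registry narrative counts: (i) carriers whose mother and father are both
   carriers (their generation is ill-defined), (ii) carriers of unknown
   sex, (iii) carriers missing the age at diagnosis / last follow-up.
   Censored carriers with a missing follow-up age are excluded under the
   same `missing_age` reason — both likelihoods need a censoring age, and
   symmetric treatment keeps them well defined.

The covariate vector is `X = (1[male], 1[MSH2], 1[MSH6], 1[PMS2])`; in the
gene–generation interaction design the scalar `Z` is replaced by
`Z* = Z * (1[MLH1], 1[MSH2], 1[MSH6], 1[PMS2])`.  Ages are continuous
years; integer ages are accepted as exact.  Follow-up is measured from
birth (no left truncation).  Families observed in a single generation are
retained: they carry no information about the generation effect directly
but inform the intercept and variance components.

## NREM: censored normal random-effects model

Onset age `T_ij = mu_i + gamma Z_ij + beta' X_ij + eps_ij` with
`mu_i ~ N(E(mu), Var(mu))` and `eps_ij ~ N(0, sigma^2)`.  A diagnosed
carrier contributes the normal density at the observed onset age; a
carrier censored at age `C` contributes the survivor function
`1 - Phi((C - m_ij)/sigma)` — the probability of being diagnosis-free at
last follow-up.  Censoring is assumed independent of onset.

The family contribution marginalises the intercept:

    L_i = \int prod_j f_ij(mu) dN(mu; E(mu), Var(mu)),

evaluated by **adaptive Gauss–Hermite quadrature** with 30 nodes.  The
integrand is log-concave (a Gaussian prior times normal densities and
survivor functions), so its mode is found by a handful of vectorised Newton
steps across all families simultaneously; nodes are centred at the mode and
scaled by the local curvature, and the quadrature sum is accumulated with
log-sum-exp.  On the study-scale fixtures the log-likelihood moves by less
than 1e-6 between 30 and 50 nodes; a Monte-Carlo oracle (1e6 draws per
family) agrees within sampling error, and with no censoring the value
matches the compound-symmetry multivariate-normal closed form to 1e-8.

Maximisation is quasi-Newton (L-BFGS-B with 3-point numerical gradients)
over `(E(mu), gamma, beta, log Var(mu), log Var(eps))` from moment-based
starting values — mean and variance of the observed onset ages, Var(mu)
started at 10% of Var(eps), regression effects at 0 — with up to three
jittered restarts on failure and a final damped Newton polish using central
differences.  Log-variance bounds are ±12, and a fit whose `log Var(mu)`
lands on the lower bound is flagged as a boundary fit rather than rejected.
Standard errors come from the observed information (numerical Hessian) at
the optimum on the estimation scale; variance SEs are transported to the
natural scale by the delta method and variance CIs are back-transformed
from the log scale, so the reported variance intervals are asymmetric.
Wald CIs are fixed at the 95% level and p-values are two-sided normal.

## COX-R: proportional hazards with a Gaussian family frailty

Hazard `lambda_0(t) exp(mu~_i + gamma~ Z_ij + beta~' X_ij)` with
`mu~_i ~ N(0, Var(mu~))` on the log-hazard scale, i.e. a log-normal shared
frailty: family baselines are proportional rather than identical.  The
baseline hazard is never parameterised; inference uses the **partial
likelihood integrated over the frailties**, approximated by Laplace:

    log IPL(theta) = pl(beta, b^) - b^'b^ / (2 theta)
                     - 1/2 log det(I + theta * H_bb),

where `b^` maximises the penalized partial log-likelihood and `H_bb` is its
information block over the frailties.  At `theta = 0` this reduces exactly
to the plain Cox partial log-likelihood, which is also available directly
(`fit_cox`) as the identical-baseline special case.  The inner problem is
solved by penalized Newton updates of fixed effects and frailty modes
jointly; the outer frailty variance by a bounded golden-section search on
the log scale over `[1e-4, 4]`, with an explicit boundary check against the
plain Cox likelihood (a collapse to zero variance is reported as such).
Fixed-effect standard errors come from the frailty-profiled block of the
penalized observed information.  Hazard ratios `exp(estimate)` are reported
to two decimals in summaries.

Ties are handled by the Efron approximation (Breslow available).  The
engine computes the gradient and information over `(beta, b)` from
suffix sums at risk-set boundaries and a weighted Gram matrix of
per-denominator risk-set sums, so a 500-family (~2100 carrier) fit takes a
few seconds.  Two cautions shape the tests: the partial likelihood is
invariant to a common shift of the linear predictor, so a single family's
frailty integrates out exactly (used as an exactness check); and it does
not factor over families — risk sets pool everyone — so replicating a
cohort does *not* double the integrated partial log-likelihood, and no such
additivity is asserted.

## Kaplan–Meier summaries

Product-limit curves of age at first diagnosis (ties processed
events-before-censorings) are computed with lifelines: exponential-
Greenwood (log-minus-log) pointwise 95% bands, median onset as the smallest
age with survival ≤ 1/2, and a median CI by inverting the confidence band.
"Median follow-up" is the reverse Kaplan–Meier median (censoring treated as
the event), the standard registry convention; with no censored subjects it
is "not reached", represented as `inf` in code and `null`/"not reached" in
exports.

## Synthetic cohort generator

The generator emulates the structure of the study cohort; its defaults are
the study conditions, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| families | 239, gene mix 96:90:39:14 | printed per-gene family counts |
| generations/family | {1: .20, 2: .30, 3: .35, 4: .10, 5: .05} | mean 2.5, range 1–5 |
| carriers/generation | 1 + Poisson(0.68), truncated at 9 | mean carriers/family ≈ 4.2 |
| sex | P(male) = 0.478 | 52.2% female carriers |
| NREM law | E(mu) 53.2, gamma −2.10, beta (0.82, −0.08, 7.83, 11.35), Var(mu) 9.53, Var(eps) 151.5 | the no-interaction estimates |
| COX-R law | gamma~ 0.171, beta~ (−0.121, 0.003, −0.655, −0.939), Var(mu~) 0.101 | the no-interaction estimates |
| baseline hazard (cox) | Weibull, shape 4, scale 55.88 | median ≈ 51 years at reference covariates |
| censoring | N(65, 15²) truncated to (0, 100), independent of onset | yields ≈ 72% diagnosed under the NREM defaults |

Under the NREM law onsets are drawn as intercept + generation shift +
covariates + noise, resampled while non-positive (the Gaussian model admits
T ≤ 0; truncation is the generator's resolution of that corner).  Under the
COX-R law onsets come from the Weibull baseline scaled by
`exp(frailty + gamma~ Z + beta~' X)` via inverse transform.  The event
indicator is `onset ≤ censor` and the recorded age is the minimum.  RNG
streams are split per family with `SeedSequence.spawn`, so enlarging a
cohort leaves earlier families byte-identical at a fixed seed.

What the generator does **not** emulate — and hence what passing
recovery tests cannot certify about real registry data: ascertainment and
referral bias, fecundity bias (fertility correlated with onset age),
birth-cohort secular trends in diagnosis age, non-independent censoring,
within-family covariate correlation beyond the shared gene, and
multiple-primary dynamics beyond a per-carrier diagnosis count.

## Problem sizes and numerical choices

Simulation-based checks use: 100 replicates of 239 families for NREM
parameter recovery (mean gamma within 0.5 years; CI coverage at binomial
tolerance), 12 replicates of 500 families for COX-R hazard-ratio recovery
(within 15%), 40 replicates of 150 families for cross-model sign coherence,
and 20 replicates of 120 families for null coverage — sizes chosen to make
the Monte-Carlo error small relative to each tolerance.  Quadrature default
is 30 adaptive nodes; the Newton mode search stops at step 1e-10; the outer
frailty-variance search uses xatol 1e-3 on the log scale.  Degenerate
inputs fail loudly: all-censored cohorts and single-family fits raise
estimation errors, constant covariates yield zero coefficients with a
ridge-stabilised solve, and singular information matrices fall back to a
pseudo-inverse with a flagged message.

## Known limitations

- Laplace is an approximation: on tiny cohorts its integrated partial
  log-likelihood sits within a few hundredths of exact quadrature; its
  frailty-variance estimate is an ML-type quantity and can differ from
  REML-flavoured implementations by more than the fixed effects do.
- No SE is reported for the frailty variance (boundary-prone, and the
  Laplace profile curvature is not a reliable one); NREM variance SEs are
  natural-scale delta-method values.
- Wald inference throughout; no likelihood-ratio or robust-sandwich
  options, no birth-cohort adjustment, no Bayesian or family-varying
  anticipation variants, no competing risks or log-rank tests.
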