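"""Cox partial likelihood, frailty integration and COX-R fitting."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import integrate, optimize
from scipy.special import logsumexp, roots_hermite

from anticipation import (
    CoxrParams,
    build_design,
    fit_cox,
    fit_coxr,
    generate_cohort,
    hazard_ratio,
    integrated_partial_loglik,
    partial_loglik,
)
from anticipation.cohort import design_arrays
from anticipation.coxr import _CoxEngine, fit_cox_arrays
from anticipation.simulate import CohortConfig


def efron_loglik(times, events, W, beta):
    """Hand-assembled Efron partial log-likelihood (independent oracle)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    W = np.atleast_2d(np.asarray(W, float))
    if W.shape[0] != times.size:
        W = W.T
    eta = W @ np.atleast_1d(beta)
    lp = 0.0
    for t in sorted(set(times[events])):
        D = np.flatnonzero((times == t) & events)
        R = np.flatnonzero(times >= t)
        d = len(D)
        sD = np.exp(eta[D]).sum()
        sR = np.exp(eta[R]).sum()
        lp += eta[D].sum()
        for l in range(d):
            lp -= math.log(sR - (l / d) * sD)
    return lp


def random_fixture(rng, n, tied=False):
    times = rng.integers(1, max(n // 2, 3), n).astype(float) if tied else rng.uniform(1, 10, n)
    events = rng.uniform(size=n) < 0.7
    if not events.any():
        events[0] = True
    W = rng.normal(0, 0.8, size=(n, 1))
    return times, events, W


# ---------------------------------------------------------------------------
# plain Cox
# ---------------------------------------------------------------------------

def test_partial_loglik_matches_hand_efron_with_ties(rng):
    times, events, W = random_fixture(rng, 20, tied=True)
    W = np.hstack([W, rng.normal(size=(20, 1))])
    for beta in ([0.0, 0.0], [0.5, -0.3], [-1.0, 0.8], [2.0, 0.1]):
        assert partial_loglik(times, events, W, beta) == pytest.approx(
            efron_loglik(times, events, W, beta), rel=1e-12, abs=1e-12
        )


@pytest.mark.parametrize("n,tied", [(8, False), (15, True), (25, True)])
def test_fit_cox_matches_bruteforce_oracle(rng, n, tied):
    """On small fixtures the fitted coefficient matches brute-force
    maximization of the explicitly assembled Efron partial likelihood."""
    times, events, W = random_fixture(rng, n, tied=tied)
    beta_hat, _, loglik, converged = fit_cox_arrays(times, events, W)
    assert converged
    res = optimize.minimize_scalar(
        lambda b: -efron_loglik(times, events, W, [b]), bounds=(-8, 8),
        method="bounded", options={"xatol": 1e-10},
    )
    assert abs(beta_hat[0]) < 5  # interior optimum, not separation
    assert beta_hat[0] == pytest.approx(res.x, abs=1e-4)
    assert loglik == pytest.approx(-res.fun, abs=1e-8)


def test_constant_covariate_gives_zero_coefficient():
    times = np.array([1.0, 2.0, 3.0, 4.0])
    events = np.array([True, True, False, True])
    W = np.ones((4, 1))
    beta, _, _, _ = fit_cox_arrays(times, events, W)
    assert beta[0] == pytest.approx(0.0, abs=1e-10)


def test_rank_invariance_under_monotone_time_transform(rng):
    times, events, W = random_fixture(rng, 25, tied=True)
    b1, *_ = fit_cox_arrays(times, events, W)
    b2, *_ = fit_cox_arrays(np.exp(times / 3.0), events, W)
    assert b1 == pytest.approx(b2, rel=1e-8)


def test_fit_cox_matches_lifelines():
    from lifelines import CoxPHFitter
    import pandas as pd

    cfg = CohortConfig(seed=5, n_families=60)
    carriers, _ = generate_cohort(cfg)
    design = build_design(carriers)
    mine = fit_cox(carriers, design)
    df = pd.DataFrame(
        {
            "T": [c.age for c in carriers],
            "E": [c.event for c in carriers],
            "Z": [d.Z for d in design],
            "male": [d.X[0] for d in design],
            "msh2": [d.X[1] for d in design],
            "msh6": [d.X[2] for d in design],
            "pms2": [d.X[3] for d in design],
        }
    )
    cph = CoxPHFitter().fit(df, "T", "E")
    assert np.allclose(list(mine.estimates.values()), cph.params_.values, atol=1e-6)
    assert np.allclose(list(mine.se.values()), cph.standard_errors_.values, atol=1e-6)
    assert mine.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)


def test_fit_cox_no_events_raises():
    from anticipation import EstimationError
    from conftest import make_carrier

    cohort = [make_carrier(f"F{i}", "a", event=False) for i in range(4)]
    with pytest.raises(EstimationError):
        fit_cox(cohort, build_design(cohort))


# ---------------------------------------------------------------------------
# integrated partial likelihood
# ---------------------------------------------------------------------------

def _small_cohort(seed, n_families):
    cfg = CohortConfig(seed=seed, n_families=n_families,
                       generations_per_family={3: 1.0},
                       carriers_per_generation={4: 1.0})
    carriers, _ = generate_cohort(cfg)
    return carriers, build_design(carriers)


def test_zero_frailty_equals_plain_partial_loglik():
    carriers, design = _small_cohort(3, 6)
    params = CoxrParams(
        gamma_tilde=0.2, beta_tilde=np.array([0.1, -0.2, 0.3, -0.4]), var_frailty=0.0
    )
    age, ev, fam, zmat, x, _ = design_arrays(carriers, design, False)
    W = np.hstack([zmat, x])
    ipl = integrated_partial_loglik(params, carriers, design)
    assert ipl == partial_loglik(age, ev, W, params.fixed_vector())


def test_single_family_frailty_integral_matches_quadrature():
    """The partial likelihood is invariant to a common shift of the linear
    predictor, so for one family the frailty integrates out exactly; the
    Laplace value must match direct numerical quadrature."""
    carriers, design = _small_cohort(7, 1)
    params = CoxrParams(
        gamma_tilde=0.2, beta_tilde=np.array([0.1, -0.1, 0.2, -0.3]), var_frailty=0.5
    )
    age, ev, fam, zmat, x, _ = design_arrays(carriers, design, False)
    W = np.hstack([zmat, x])
    engine = _CoxEngine(age, ev, W, fam, n_fam=1)
    beta = params.fixed_vector()
    sd = math.sqrt(params.var_frailty)

    def integrand(b):
        return math.exp(engine.loglik(np.concatenate([beta, [b]]))) * (
            math.exp(-0.5 * (b / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        )

    exact, _ = integrate.quad(integrand, -8 * sd, 8 * sd)
    ipl = integrated_partial_loglik(params, carriers, design)
    assert ipl == pytest.approx(math.log(exact), abs=1e-3)


def test_two_family_laplace_close_to_exact_quadrature():
    """Laplace is an approximation; on a tiny two-family cohort it should sit
    within a few hundredths of the exact (tensor Gauss-Hermite) integral."""
    carriers, design = _small_cohort(7, 2)
    params = CoxrParams(
        gamma_tilde=0.2, beta_tilde=np.array([0.1, -0.1, 0.2, -0.3]), var_frailty=0.3
    )
    age, ev, fam, zmat, x, _ = design_arrays(carriers, design, False)
    engine = _CoxEngine(age, ev, np.hstack([zmat, x]), fam, n_fam=2)
    beta = params.fixed_vector()
    xk, wk = roots_hermite(60)
    s = math.sqrt(2 * params.var_frailty)
    vals = [
        math.log(wk[i] * wk[j] / math.pi)
        + engine.loglik(np.concatenate([beta, [xk[i] * s, xk[j] * s]]))
        for i in range(60)
        for j in range(60)
    ]
    exact = logsumexp(vals)
    ipl = integrated_partial_loglik(params, carriers, design)
    assert ipl == pytest.approx(exact, abs=0.05)


def test_negative_frailty_variance_rejected():
    with pytest.raises(ValueError):
        CoxrParams(gamma_tilde=0.1, beta_tilde=np.zeros(4), var_frailty=-0.1)


# ---------------------------------------------------------------------------
# COX-R fitting
# ---------------------------------------------------------------------------

def test_coxr_fixed_zero_variance_equals_plain_cox(default_cohort, default_design):
    _, carriers, _ = default_cohort
    frailty0 = fit_coxr(carriers, default_design, fix_var_frailty=0.0)
    plain = fit_cox(carriers, default_design)
    assert frailty0.collapsed
    for (kf, vf), (kp, vp) in zip(frailty0.estimates.items(), plain.estimates.items()):
        if kf == "var_frailty":
            continue
        assert vf == pytest.approx(vp, abs=1e-6)
    assert all(abs(b) < 1e-12 for b in frailty0.frailty_modes.values())


def test_coxr_recovers_on_cox_generated_cohort():
    cfg = CohortConfig(seed=42, n_families=300, generative_model="cox")
    carriers, _ = generate_cohort(cfg)
    design = build_design(carriers)
    fit = fit_coxr(carriers, design)
    assert fit.converged
    lo, hi = fit.ci95["gamma_tilde"]
    assert lo < cfg.cox_params.gamma_tilde < hi
    assert abs(np.mean(list(fit.frailty_modes.values()))) < 1e-8
    assert fit.anticipation is bool(fit.estimates["gamma_tilde"] > 0)


def test_null_simulation_coverage():
    """With no generational or family effect, the gamma~ CI should cover 0
    in the large majority of replicates."""
    base = CohortConfig(generative_model="cox", n_families=120)
    null_cox = dataclasses.replace(
        base.cox_params, gamma_tilde=0.0, var_frailty=0.0
    )
    covered = 0
    n_rep = 20
    for s in range(n_rep):
        cfg = dataclasses.replace(base, cox_params=null_cox, seed=9000 + s)
        carriers, _ = generate_cohort(cfg)
        fit = fit_coxr(carriers, build_design(carriers))
        lo, hi = fit.ci95["gamma_tilde"]
        covered += lo < 0.0 < hi
    assert covered >= 16  # ~95% nominal; binomial slack at 20 replicates


# ---------------------------------------------------------------------------
# hazard-ratio reporting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "loghr,hr", [(0.171, 1.19), (0.0, 1.00), (0.618, 1.86), (0.284, 1.33)]
)
def test_hazard_ratio_two_decimals(loghr, hr):
    assert round(hazard_ratio(loghr), 2) == hr


def test_breslow_cumulative_hazard_matches_lifelines():
    from lifelines import CoxPHFitter
    import pandas as pd
    from anticipation.coxr import breslow_cumulative_hazard

    cfg = CohortConfig(seed=5, n_families=40)
    carriers, _ = generate_cohort(cfg)
    design = build_design(carriers)
    fit = fit_cox(carriers, design)
    times, cumhaz = breslow_cumulative_hazard(carriers, design, fit)
    assert times.size > 0 and np.all(np.diff(cumhaz) > 0)
    df = pd.DataFrame(
        {
            "T": [c.age for c in carriers],
            "E": [c.event for c in carriers],
            "Z": [d.Z for d in design],
            "male": [d.X[0] for d in design],
            "msh2": [d.X[1] for d in design],
            "msh6": [d.X[2] for d in design],
            "pms2": [d.X[3] for d in design],
        }
    )
    cph = CoxPHFitter(baseline_estimation_method="breslow").fit(df, "T", "E")
    # lifelines reports the baseline at the covariate means, ours at zero
    xbar = df[["Z", "male", "msh2", "msh6", "pms2"]].mean().to_numpy()
    ours = cumhaz * np.exp(xbar @ cph.params_.to_numpy())
    theirs = cph.baseline_cumulative_hazard_.iloc[:, 0]
    theirs = np.interp(times, theirs.index.to_numpy(), theirs.to_numpy())
    assert np.allclose(ours, theirs, rtol=1e-4)
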