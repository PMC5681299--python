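"""Normal random-effects model (NREM) of genetic anticipation.

Age at first diagnosis for carrier j of family i is modelled as

    T_ij = mu_i + gamma * Z_ij + beta' X_ij + eps_ij,

with a family-specific random intercept mu_i ~ N(E(mu), Var(mu)) and
residual eps_ij ~ N(0, sigma^2).  Z_ij is the carrier's generation depth
(0 = oldest observed generation of the family), so gamma is the mean change
in onset age per generation and anticipation is indicated by gamma < 0.
In the gene-generation interaction variant the scalar Z is replaced by the
4-vector Z * (1[MLH1], 1[MSH2], 1[MSH6], 1[PMS2]) giving one anticipation
effect per mismatch-repair gene.

Carriers not yet diagnosed at last follow-up contribute the normal survivor
function (the probability of being diagnosis-free at the censoring age);
censoring is assumed independent of onset.  The family random intercept is
integrated out by adaptive Gauss-Hermite quadrature (mode- and
curvature-rescaled per family), and the marginal likelihood is maximised by
quasi-Newton optimisation with variances parameterised on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special
from scipy.special import log_ndtr, logsumexp
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .cohort import GENES, CarrierRecord, DesignRow, EstimationError, design_arrays

__all__ = [
    "NremParams",
    "NremFit",
    "family_marginal_loglik",
    "cohort_loglik",
    "fit_nrem",
    "wald_test",
]

_LOG_2PI = math.log(2.0 * math.pi)
_LOGVAR_LO, _LOGVAR_HI = -12.0, 12.0  # bounds for log-variances during fitting
_VAR_MU_FLOOR = 1e-8  # below this, the random intercept is treated as absent


@dataclass
class NremParams:
    """NREM parameters on the natural scale.

    ``gamma`` is a scalar (years per generation) in the no-interaction model
    or a length-4 array (MLH1, MSH2, MSH6, PMS2) in the interaction model;
    ``beta`` is the effect 4-vector for (male, MSH2, MSH6, PMS2).
    """

    mu_mean: float
    gamma: float | np.ndarray
    beta: np.ndarray
    var_mu: float
    var_eps: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (4,):
            raise ValueError("beta must be a length-4 vector")
        if np.ndim(self.gamma) not in (0, 1):
            raise ValueError("gamma must be a scalar or a length-4 vector")
        if np.ndim(self.gamma) == 1:
            self.gamma = np.asarray(self.gamma, dtype=float)
            if self.gamma.shape != (4,):
                raise ValueError("vector gamma must have length 4")
        if self.var_eps <= 0:
            raise ValueError("var_eps must be positive")
        if self.var_mu < 0:
            raise ValueError("var_mu must be non-negative")

    @property
    def interactions(self) -> bool:
        return np.ndim(self.gamma) == 1

    def gamma_vector(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.gamma, dtype=float))


@dataclass
class NremFit:
    params: NremParams
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    wald_p: dict[str, float]
    loglik: float
    converged: bool
    n_quadrature: int
    boundary_var_mu: bool = False
    message: str = ""
    n_carriers: int = 0
    n_families: int = 0

    @property
    def estimates(self) -> dict[str, float]:
        """Point estimates keyed like ``se``/``ci95`` (variances on the
        natural scale)."""
        p = self.params
        out = {"E(mu)": p.mu_mean}
        if p.interactions:
            out.update({f"gamma_{g}": float(v) for g, v in zip(GENES, p.gamma)})
        else:
            out["gamma"] = float(p.gamma)
        out.update(
            dict(zip(["beta_male", "beta_MSH2", "beta_MSH6", "beta_PMS2"], p.beta))
        )
        out["var_mu"] = p.var_mu
        out["var_eps"] = p.var_eps
        return out

    @property
    def anticipation(self) -> bool | dict[str, bool]:
        """Anticipation is indicated by gamma < 0."""
        g = self.params.gamma
        if np.ndim(g) == 0:
            return bool(g < 0)
        return {gene: bool(v < 0) for gene, v in zip(GENES, g)}


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _std_logpdf(z: np.ndarray) -> np.ndarray:
    return -0.5 * (z * z) - 0.5 * _LOG_2PI


def _log_sf(z: np.ndarray) -> np.ndarray:
    """log(1 - Phi(z)), numerically stable."""
    return log_ndtr(-z)


def _hazard(z: np.ndarray) -> np.ndarray:
    """phi(z) / (1 - Phi(z)), the standard normal hazard."""
    return np.exp(_std_logpdf(z) - _log_sf(z))


class _FamilyData:
    """Cohort flattened into family-sorted arrays for vectorised quadrature."""

    def __init__(self, age, event, fam_idx, zmat, x):
        order = np.argsort(fam_idx, kind="stable")
        self.age = np.asarray(age, float)[order]
        self.event = np.asarray(event, bool)[order]
        fam = np.asarray(fam_idx)[order]
        self.zmat = np.asarray(zmat, float)[order]
        self.x = np.asarray(x, float)[order]
        self.n = self.age.size
        uniq, starts = np.unique(fam, return_index=True)
        self.starts = starts
        self.n_families = uniq.size

    def fam_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts)


def _marginal_logliks(
    data: _FamilyData,
    params: NremParams,
    n_quadrature: int,
    nodes: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-family log marginal likelihood via adaptive Gauss-Hermite.

    The integrand over the random-intercept deviation b is log-concave
    (Gaussian density times normal densities/survivor functions), so a few
    undamped Newton steps locate its mode; nodes are then centred at the
    mode and scaled by the curvature.
    """
    sigma = math.sqrt(params.var_eps)
    tau2 = params.var_mu
    fixed = data.zmat @ params.gamma_vector() + data.x @ params.beta
    r = data.age - params.mu_mean - fixed  # residual w.r.t. fixed effects

    ev = data.event
    cn = ~ev

    def conditional_terms(b_per_carrier: np.ndarray) -> np.ndarray:
        """log density / log survivor contribution per carrier given b."""
        z = (r - b_per_carrier) / sigma
        out = np.empty_like(z)
        out[ev] = _std_logpdf(z[ev]) - math.log(sigma)
        out[cn] = _log_sf(z[cn])
        return out

    if tau2 < _VAR_MU_FLOOR:
        return data.fam_sum(conditional_terms(np.zeros(data.n)))

    # --- Newton mode search, all families at once ---
    starts = data.starts
    b = np.zeros(data.n_families)
    for _ in range(60):
        bc = np.repeat(b, np.diff(np.append(starts, data.n)))
        z = (r - bc) / sigma
        d1 = np.zeros(data.n)
        d2 = np.zeros(data.n)
        d1[ev] = z[ev] / sigma
        d2[ev] = -1.0 / params.var_eps
        h = _hazard(z[cn])
        d1[cn] = h / sigma
        d2[cn] = -h * (h - z[cn]) / params.var_eps
        g1 = data.fam_sum(d1) - b / tau2
        g2 = data.fam_sum(d2) - 1.0 / tau2
        step = -g1 / g2
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    curvature = -g2  # positive, by log-concavity
    scale = 1.0 / np.sqrt(curvature)

    if nodes is None:
        nodes = special.roots_hermite(n_quadrature)
    xk, wk = nodes
    # quadrature points per family: b_fk = mode_f + sqrt(2) * scale_f * x_k
    bfk = b[:, None] + math.sqrt(2.0) * scale[:, None] * xk[None, :]
    bc = np.repeat(bfk, np.diff(np.append(starts, data.n)), axis=0)  # (n, K)
    z = (r[:, None] - bc) / sigma
    terms = np.empty_like(z)
    terms[ev] = _std_logpdf(z[ev]) - math.log(sigma)
    terms[cn] = _log_sf(z[cn])
    g = np.add.reduceat(terms, starts, axis=0)  # (F, K) carrier sums
    g += -0.5 * _LOG_2PI - 0.5 * math.log(tau2) - bfk**2 / (2.0 * tau2)  # prior
    log_w = np.log(wk)[None, :] + xk[None, :] ** 2 + g
    return logsumexp(log_w, axis=1) + 0.5 * math.log(2.0) + np.log(scale)


def family_marginal_loglik(
    params: NremParams,
    ages: Sequence[float],
    events: Sequence[bool],
    design: Sequence[DesignRow],
    n_quadrature: int = 30,
) -> float:
    """Marginal log-likelihood contribution of a single family.

    Integrates the product of per-carrier normal densities (events) and
    survivor functions (censored carriers) over the family random intercept.
    An empty family contributes 0.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        return 0.0
    events = np.asarray(events, dtype=bool)
    if params.interactions:
        zmat = np.array([row.Zstar for row in design], dtype=float)
    else:
        zmat = np.array([[row.Z] for row in design], dtype=float)
    x = np.array([row.X for row in design], dtype=float)
    data = _FamilyData(ages, events, np.zeros(ages.size, dtype=np.intp), zmat, x)
    return float(_marginal_logliks(data, params, n_quadrature)[0])


def cohort_loglik(
    params: NremParams,
    cohort: Sequence[CarrierRecord],
    design: Sequence[DesignRow],
    n_quadrature: int = 30,
) -> float:
    """Cohort log-likelihood: sum of independent family contributions."""
    age, event, fam_idx, zmat, x, _ = design_arrays(
        cohort, design, interactions=params.interactions
    )
    data = _FamilyData(age, event, fam_idx, zmat, x)
    return float(_marginal_logliks(data, params, n_quadrature).sum())


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _pack(params: NremParams, fix_var_mu: float | None) -> np.ndarray:
    theta = [params.mu_mean, *np.atleast_1d(params.gamma), *params.beta]
    if fix_var_mu is None:
        theta.append(math.log(max(params.var_mu, _VAR_MU_FLOOR)))
    theta.append(math.log(params.var_eps))
    return np.asarray(theta, dtype=float)


def _unpack(theta: np.ndarray, interactions: bool, fix_var_mu: float | None) -> NremParams:
    k = 4 if interactions else 1
    gamma = theta[1 : 1 + k] if interactions else float(theta[1])
    beta = theta[1 + k : 5 + k]
    if fix_var_mu is None:
        var_mu = math.exp(theta[5 + k])
        var_eps = math.exp(theta[6 + k])
    else:
        var_mu = fix_var_mu
        var_eps = math.exp(theta[5 + k])
    return NremParams(float(theta[0]), gamma, beta, var_mu, var_eps)


def _param_names(interactions: bool, fix_var_mu: float | None) -> list[str]:
    names = ["E(mu)"]
    names += [f"gamma_{g}" for g in GENES] if interactions else ["gamma"]
    names += ["beta_male", "beta_MSH2", "beta_MSH6", "beta_PMS2"]
    if fix_var_mu is None:
        names.append("var_mu")
    names.append("var_eps")
    return names


def _newton_polish(negloglik, theta, bounds, max_iter: int = 6) -> np.ndarray:
    """A few damped Newton steps with numerical derivatives to sharpen the
    quasi-Newton optimum (finite-difference gradients limit L-BFGS-B)."""
    f0 = negloglik(theta)
    for _ in range(max_iter):
        grad = approx_fprime(theta, negloglik, centered=True)
        hess = approx_hess(theta, negloglik)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(10):
            cand = theta - scale * step
            for i, (lo, hi) in enumerate(bounds):
                if lo is not None:
                    cand[i] = max(cand[i], lo)
                if hi is not None:
                    cand[i] = min(cand[i], hi)
            f1 = negloglik(cand)
            if f1 <= f0 + 1e-12:
                break
            scale *= 0.5
        else:
            break
        theta, moved = cand, f0 - f1
        f0 = f1
        if np.max(np.abs(scale * step)) < 1e-10 or moved < 1e-13:
            break
    return theta


def fit_nrem(
    cohort: Sequence[CarrierRecord],
    design: Sequence[DesignRow],
    interactions: bool = False,
    n_quadrature: int = 30,
    fix_var_mu: float | None = None,
    max_restarts: int = 3,
    seed: int = 0,
) -> NremFit:
    """Fit the NREM by marginal maximum likelihood.

    Variances are optimised on the log scale; standard errors come from the
    observed information at the optimum, with variance SEs transported to
    the natural scale by the delta method and variance CIs back-transformed
    from the log scale.  ``fix_var_mu`` pins Var(mu) (e.g. at 0 to drop the
    random intercept).
    """
    age, event, fam_idx, zmat, x, _ = design_arrays(cohort, design, interactions)
    data = _FamilyData(age, event, fam_idx, zmat, x)
    if data.n_families < 2:
        raise EstimationError("fit_nrem requires at least 2 families")
    if not event.any():
        raise EstimationError("all carriers censored: onset location not estimable")

    nodes = special.roots_hermite(n_quadrature)
    k = 4 if interactions else 1

    def negloglik(theta: np.ndarray) -> float:
        params = _unpack(theta, interactions, fix_var_mu)
        ll = _marginal_logliks(data, params, n_quadrature, nodes).sum()
        return -ll if np.isfinite(ll) else 1e12

    # moment starts: mean/variance of observed onset ages
    obs = age[event]
    v0 = max(float(np.var(obs)), 1.0)
    start_params = NremParams(
        mu_mean=float(np.mean(obs)),
        gamma=np.zeros(4) if interactions else 0.0,
        beta=np.zeros(4),
        var_mu=fix_var_mu if fix_var_mu is not None else 0.1 * v0,
        var_eps=v0,
    )
    theta0 = _pack(start_params, fix_var_mu)
    n_logvar = 1 if fix_var_mu is not None else 2
    bounds = [(None, None)] * (5 + k) + [(_LOGVAR_LO, _LOGVAR_HI)] * n_logvar

    rng = np.random.default_rng(seed)
    best = None
    message = ""
    for attempt in range(max_restarts + 1):
        t0 = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.3, size=theta0.size)
        res = optimize.minimize(
            negloglik, t0, method="L-BFGS-B", bounds=bounds, jac="3-point",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success:
            best = res if res.fun <= best.fun + 1e-9 else best
            break
        message = str(res.message)
    assert best is not None
    converged = bool(best.success)
    theta_hat = _newton_polish(negloglik, best.x, bounds)
    params = _unpack(theta_hat, interactions, fix_var_mu)
    loglik = -float(best.fun)

    boundary = fix_var_mu is None and theta_hat[5 + k] <= _LOGVAR_LO + 0.1
    if boundary:
        message = (message + " " if message else "") + "Var(mu) at the zero boundary"

    # observed information on the estimation scale (log variances)
    names = _param_names(interactions, fix_var_mu)
    se: dict[str, float] = {}
    ci95: dict[str, tuple[float, float]] = {}
    wald_p: dict[str, float] = {}
    try:
        hess = approx_hess(theta_hat, negloglik)
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive variance estimates")
        se_theta = np.sqrt(diag)
    except np.linalg.LinAlgError:
        converged = False
        message = (message + " " if message else "") + "observed information not invertible"
        se_theta = np.full(theta_hat.size, np.nan)

    for i, name in enumerate(names):
        est = theta_hat[i]
        s = se_theta[i]
        if name.startswith("var_"):
            natural = math.exp(est)
            se[name] = natural * s  # delta method
            with np.errstate(over="ignore"):  # upper limit may be inf at a boundary
                ci95[name] = (
                    float(np.exp(est - 1.96 * s)),
                    float(np.exp(est + 1.96 * s)),
                )
        else:
            se[name] = s
            ci95[name] = (est - 1.96 * s, est + 1.96 * s)
            wald_p[name] = wald_test(est, s)[1] if np.isfinite(s) and s > 0 else math.nan

    return NremFit(
        params=params,
        se=se,
        ci95=ci95,
        wald_p=wald_p,
        loglik=loglik,
        converged=converged,
        n_quadrature=n_quadrature,
        boundary_var_mu=boundary,
        message=message,
        n_carriers=data.n,
        n_families=data.n_families,
    )


def wald_test(estimate: float, se: float) -> tuple[float, float]:
    """Wald z-statistic and two-sided p-value, p = 2(1 - Phi(|z|))."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    p = 2.0 * math.exp(_log_sf(np.array(abs(z))))
    return float(z), float(min(p, 1.0))
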