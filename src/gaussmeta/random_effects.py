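"""Random-effects meta-analysis (study-specific residual variances).

Model: y_ij = (alpha + a_i) + (beta + b_i) x_ij + eps_ij with fixed study
intercepts, random treatment effects b_i ~ N(0, tau2) and study-specific
residual variances eps_ij ~ N(0, sigma_i^2).

Two procedures fit this model:

* two-stage: reduce each study to (beta_hat_i, v_i), then REML for tau2 in
  beta_hat_i ~ N(beta, tau2 + v_i) with the v_i treated as fixed and known;
* one-stage: joint REML over (tau2, sigma_1^2, ..., sigma_I^2) on the
  patient-level data, here carried out on collapsed per-study sufficient
  statistics.  Collapsing is exact: for this model the restricted
  log-likelihood reduces (up to a constant) to

      -2 l_R = sum_i [(n_i-2) log sigma_i^2 + RSS_i / sigma_i^2]
               + sum_i log(tau2 + c_i sigma_i^2) + log(sum_i u_i)
               + sum_i u_i (d_i - beta_tilde)^2,

  with d_i the arm-mean difference, c_i = 1/n_t + 1/n_c,
  u_i = 1/(tau2 + c_i sigma_i^2) and beta_tilde the u-weighted mean.  The
  extra arm-sum coordinate that carries the treatment effect when arms are
  unbalanced cancels exactly against the fixed-intercept determinant term,
  so no balance assumption is needed.

Small-sample inference uses the Kenward-Roger correction specialised to a
scalar fixed effect: with Phi = (1'V^-1 1)^-1, P_r = 1'(dV^-1/dtheta_r)1,
Q_rs = 1'(dV^-1/dtheta_r) V (dV^-1/dtheta_s) 1 and W the inverse (expected
or observed) information of the variance parameters,

    Phi_A = Phi + 2 Phi^2 sum_rs W_rs (Q_rs - Phi P_r P_s),
    df    = 2 / (Phi^2 sum_rs W_rs P_r P_s),

the degrees of freedom being the Satterthwaite-type quantity
2 Phi^2 / Var_hat(Phi_hat) to which the full Kenward-Roger df collapses for
a single contrast.  In the balanced equal-v case this yields
Phi_A = S^2/I and df = I - 1, i.e. the ordinary t-interval on the study
estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data import (
    AggregateDataset,
    IPDDataset,
    MetaResult,
    MethodInfo,
    as_aggregate,
    make_result,
    summarize_studies,
)
from .errors import ConvergenceError, DegenerateStudyError

logger = logging.getLogger("gaussmeta")

__all__ = [
    "REMLFit",
    "reml_tau2",
    "kr_adjust_two_stage",
    "fit_two_stage_re",
    "fit_one_stage_re",
    "one_stage_restricted_loglik",
]

#: convergence tolerances (relative log-likelihood change / parameter)
REML_TOL = 1e-10
REML_MAXITER = 200


@dataclass(frozen=True)
class REMLFit:
    """Result of a REML fit of the random-effects model."""

    tau2_hat: float
    beta_hat: float
    var_naive: float
    var_adjusted: float
    df_kr: float
    information: str
    converged: bool
    iterations: int
    loglik: float
    procedure: str
    sigma2_hats: np.ndarray | None = None  # one-stage only


# ---------------------------------------------------------------------------
# Two-stage REML
# ---------------------------------------------------------------------------

def _profile_restricted_loglik(tau2: float, b: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of beta_hat_i ~ N(beta, tau2 + v_i), beta profiled."""
    g = tau2 + v
    if np.any(g <= 0):
        return -np.inf
    u = 1.0 / g
    U = u.sum()
    bt = np.sum(u * b) / U
    return -0.5 * (np.sum(np.log(g)) + math.log(U) + np.sum(u * (b - bt) ** 2))


def reml_tau2(agg, *, return_trace: bool = False):
    """REML estimate of the between-study variance tau2 (boundary at 0 allowed).

    Maximises the restricted log-likelihood by bounded scalar optimisation;
    the search interval spans [0, ~10x the spread of the study estimates].
    """
    agg = as_aggregate(agg)
    b, v = agg.beta_hats, agg.v
    if agg.n_studies < 2:
        raise DegenerateStudyError("REML needs at least 2 studies")
    spread = float(np.var(b, ddof=1))
    hi = 10.0 * (spread + float(np.max(v))) + 1e-12

    neg = lambda t: -_profile_restricted_loglik(t, b, v)
    res = optimize.minimize_scalar(
        neg, bounds=(0.0, hi), method="bounded",
        options={"xatol": 1e-12 * (1.0 + hi), "maxiter": 500},
    )
    if not res.success:
        raise ConvergenceError("two-stage REML did not converge", trace=res)
    tau2 = float(res.x)
    # the bounded minimiser can sit just inside the boundary; snap if 0 is better
    if neg(0.0) <= res.fun:
        tau2 = 0.0
    if return_trace:
        return tau2, res
    return tau2


def _kr_scalar(Phi, P_vec, Q_mat, W):
    """Kenward-Roger adjusted variance and df for a scalar fixed effect."""
    P_vec = np.atleast_1d(np.asarray(P_vec, float))
    Q_mat = np.atleast_2d(np.asarray(Q_mat, float))
    W = np.atleast_2d(np.asarray(W, float))
    adj = 2.0 * Phi**2 * float(np.sum(W * (Q_mat - Phi * np.outer(P_vec, P_vec))))
    var_adj = Phi + adj
    A = Phi**2 * float(P_vec @ W @ P_vec)
    if A <= 0:
        logger.warning("non-positive curvature term in KR df; using normal df")
        return max(var_adj, Phi), math.inf
    df = 2.0 / A
    if df < 1.0:
        logger.warning("KR df %.3g below 1; flooring at 1", df)
        df = 1.0
    return max(var_adj, Phi), df


def _expected_info_tau2(u: np.ndarray) -> float:
    U = u.sum()
    s2, s3 = np.sum(u**2), np.sum(u**3)
    return 0.5 * (s2 - 2.0 * s3 / U + s2**2 / U**2)


def kr_adjust_two_stage(agg, tau2_hat: float, information: str = "expected"):
    """KR-adjusted variance and df for the two-stage REML pooled effect.

    Returns ``(var_adjusted, df_kr)``.  The information matrix of tau2 is
    expected (default, the customary two-stage choice) or observed (numeric
    curvature of the restricted likelihood at tau2_hat).
    """
    agg = as_aggregate(agg)
    b, v = agg.beta_hats, agg.v
    u = 1.0 / (tau2_hat + v)
    U = u.sum()
    Phi = 1.0 / U
    P = -float(np.sum(u**2))
    Q = float(np.sum(u**3))

    info = _expected_info_tau2(u)
    if information == "observed":
        h = 1e-5 * (tau2_hat + float(np.median(v)))
        f = lambda t: _profile_restricted_loglik(t, b, v)
        if tau2_hat - h + v.min() > 0:
            obs = -(f(tau2_hat + h) - 2 * f(tau2_hat) + f(tau2_hat - h)) / h**2
        else:  # one-sided at the tau2 = 0 boundary
            obs = -(f(tau2_hat + 2 * h) - 2 * f(tau2_hat + h) + f(tau2_hat)) / h**2
        if obs > 0:
            info = obs
        else:
            logger.warning(
                "observed information non-positive at tau2=%.3g; "
                "falling back to expected information", tau2_hat,
            )
    elif information != "expected":
        raise ValueError(f"unknown information type {information!r}")
    W = 1.0 / info
    return _kr_scalar(Phi, [P], [[Q]], [[W]])


def fit_two_stage_re(
    data, level: float = 0.95, information: str = "expected"
) -> tuple[REMLFit, MetaResult]:
    """Two-stage random-effects meta-analysis: REML tau2, then KR-adjusted CI."""
    agg = as_aggregate(data)
    tau2, trace = reml_tau2(agg, return_trace=True)
    b, v = agg.beta_hats, agg.v
    u = 1.0 / (tau2 + v)
    U = u.sum()
    beta = float(np.sum(u * b) / U)
    var_naive = 1.0 / U
    var_adj, df = kr_adjust_two_stage(agg, tau2, information)
    fit = REMLFit(
        tau2_hat=tau2,
        beta_hat=beta,
        var_naive=var_naive,
        var_adjusted=var_adj,
        df_kr=df,
        information=information,
        converged=True,
        iterations=int(getattr(trace, "nfev", 0)),
        loglik=_profile_restricted_loglik(tau2, b, v),
        procedure="two_stage",
    )
    method = MethodInfo(
        model="V", procedure="two_stage", residual_variance="study_specific",
        correction="kenward_roger", information=information,
    )
    result = make_result(beta, var_adj, level, df, method, tau2_hat=tau2)
    return fit, result


# ---------------------------------------------------------------------------
# One-stage REML on collapsed sufficient statistics
# ---------------------------------------------------------------------------

def _collapse(data: IPDDataset):
    summaries = summarize_studies(data)
    d = np.array([s.beta_hat for s in summaries])
    c = np.array([s.c for s in summaries])
    m = np.array([s.df_resid for s in summaries], dtype=float)
    rss = np.array([s.df_resid * s.sigma2_hat for s in summaries])
    if np.any(rss <= 0):
        raise DegenerateStudyError(
            "one-stage REML needs positive within-study residual variation"
        )
    return d, c, m, rss, summaries


def _neg_loglik_and_grad(tau2, s2, d, c, m, rss):
    """-l_R (up to a constant) and its gradient wrt (tau2, sigma2 vector)."""
    g = tau2 + c * s2
    if np.any(g <= 0) or np.any(s2 <= 0):
        return np.inf, None
    u = 1.0 / g
    U = u.sum()
    bt = np.sum(u * d) / U
    r = d - bt
    f = 0.5 * (
        np.sum(m * np.log(s2) + rss / s2)
        + np.sum(np.log(g))
        + math.log(U)
        + np.sum(u * r**2)
    )
    dldg = 0.5 * (u - u**2 / U - u**2 * r**2)  # envelope: beta profiled out
    grad_t = float(np.sum(dldg))
    grad_s = 0.5 * (m / s2 - rss / s2**2) + c * dldg
    return f, np.concatenate([[grad_t], grad_s])


def one_stage_restricted_loglik(data: IPDDataset, tau2: float, sigma2) -> float:
    """Restricted log-likelihood (up to a constant) at given variance values."""
    d, c, m, rss, _ = _collapse(data)
    s2 = np.broadcast_to(np.asarray(sigma2, float), d.shape).copy()
    f, _ = _neg_loglik_and_grad(float(tau2), s2, d, c, m, rss)
    return -f


def _pack_theta(tau2, s2, shared):
    return np.concatenate([[tau2], [float(np.mean(s2))] if shared else s2])


def _expected_info_one_stage(tau2, s2, c, m, shared):
    """Expected REML information of (tau2, sigma2 params) at the given point."""
    g = tau2 + c * s2
    u = 1.0 / g
    U = u.sum()

    def tr_term(a, b):
        return (
            np.sum(u**2 * a * b)
            - 2.0 * np.sum(u**3 * a * b) / U
            + np.sum(u**2 * a) * np.sum(u**2 * b) / U**2
        )

    I = len(c)
    if shared:
        # parameters (tau2, sigma2) with dD/dsigma2 = diag(c)
        ones = np.ones(I)
        H = np.empty((2, 2))
        H[0, 0] = 0.5 * tr_term(ones, ones)
        H[0, 1] = H[1, 0] = 0.5 * tr_term(ones, c)
        H[1, 1] = 0.5 * tr_term(c, c) + np.sum(m) / (2.0 * s2[0] ** 2)
        return H
    H = np.empty((I + 1, I + 1))
    H[0, 0] = 0.5 * tr_term(np.ones(I), np.ones(I))
    for i in range(I):
        a = np.zeros(I)
        a[i] = c[i]
        H[0, i + 1] = H[i + 1, 0] = 0.5 * tr_term(np.ones(I), a)
        for j in range(i, I):
            b_ = np.zeros(I)
            b_[j] = c[j]
            H[i + 1, j + 1] = H[j + 1, i + 1] = 0.5 * tr_term(a, b_)
        H[i + 1, i + 1] += m[i] / (2.0 * s2[i] ** 2)
    return H


def _observed_info(theta, d, c, m, rss, shared, free_tau2=True):
    """Numeric Hessian of -l_R by central differences of the analytic gradient."""
    k = theta.size

    def grad(th):
        tau2 = th[0]
        s2 = np.full(len(c), th[1]) if shared else th[1:]
        f, gr = _neg_loglik_and_grad(tau2, s2, d, c, m, rss)
        if gr is None:
            raise ConvergenceError("non-finite likelihood while differentiating")
        if shared:
            gr = np.array([gr[0], np.sum(gr[1:])])
        return gr

    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * (abs(theta[j]) + 1e-3)
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        try:
            H[:, j] = (grad(up) - grad(dn)) / (2 * h)
        except ConvergenceError:
            dn = theta.copy()  # one-sided at a boundary
            H[:, j] = (grad(up) - grad(theta)) / h
    H = 0.5 * (H + H.T)
    if not free_tau2:
        H = H[1:, 1:]
    return H


def fit_one_stage_re(
    data: IPDDataset,
    level: float = 0.95,
    information: str = "observed",
    *,
    shared_sigma2: bool = False,
    fix_tau2: float | None = None,
) -> tuple[REMLFit, MetaResult]:
    """One-stage REML fit of the random-effects model with KR-adjusted CI.

    Residual variances are re-estimated jointly with tau2 (the defining
    difference from the two-stage procedure, whose stage-1 variances are
    plugged in as known).  ``information`` defaults to observed, the
    customary one-stage choice.  ``shared_sigma2`` constrains all residual
    variances equal; ``fix_tau2`` pins the between-study variance (both are
    mainly diagnostic devices — with both constraints the fit collapses to
    the ordinary least-squares fixed-effect model).
    """
    if data.n_studies < 2:
        raise DegenerateStudyError("one-stage REML needs at least 2 studies")
    d, c, m, rss, summaries = _collapse(data)
    I = len(d)

    # initialise at the two-stage solution
    s2_init = rss / m
    agg = AggregateDataset.from_summaries(summaries)
    tau2_init = fix_tau2 if fix_tau2 is not None else reml_tau2(agg)
    free_tau2 = fix_tau2 is None

    if shared_sigma2:
        z0 = np.array([math.log(float(np.sum(rss) / np.sum(m)))])
    else:
        z0 = np.log(s2_init)
    x0 = np.concatenate([[tau2_init], z0]) if free_tau2 else z0

    def unpack(x):
        if free_tau2:
            tau2, z = x[0], x[1:]
        else:
            tau2, z = fix_tau2, x
        s2 = np.full(I, math.exp(z[0])) if shared_sigma2 else np.exp(z)
        return float(tau2), s2

    def objective(x):
        tau2, s2 = unpack(x)
        f, gr = _neg_loglik_and_grad(tau2, s2, d, c, m, rss)
        if gr is None:
            return np.inf, np.zeros_like(x)
        gs = gr[1:] * s2  # chain rule for log-variance parameters
        if shared_sigma2:
            gs = np.array([np.sum(gs)])
        g = np.concatenate([[gr[0]], gs]) if free_tau2 else gs
        return f, g

    bounds = ([(0.0, None)] if free_tau2 else []) + [(None, None)] * z0.size
    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": REML_MAXITER, "ftol": REML_TOL, "gtol": 1e-9},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError("one-stage REML reached a non-finite likelihood",
                               trace=res)
    if not res.success and np.linalg.norm(res.jac) > 1e-4:
        raise ConvergenceError(f"one-stage REML did not converge: {res.message}",
                               trace=res)
    tau2, s2 = unpack(res.x)

    g = tau2 + c * s2
    u = 1.0 / g
    U = u.sum()
    beta = float(np.sum(u * d) / U)
    Phi = 1.0 / U

    # KR building blocks in the collapsed arm-difference representation
    if free_tau2:
        P_vec = [-float(np.sum(u**2))]
        Q_rows = [[float(np.sum(u**3))]]
    else:
        P_vec, Q_rows = [], []
    if shared_sigma2:
        P_s = [-float(np.sum(c * u**2))]
        if free_tau2:
            Q_rows[0].append(float(np.sum(c * u**3)))
            Q_rows.append([float(np.sum(c * u**3)), float(np.sum(c**2 * u**3))])
        else:
            Q_rows.append([float(np.sum(c**2 * u**3))])
        P_vec = P_vec + P_s
        Q = np.array(Q_rows)
    else:
        P_sig = -c * u**2
        if free_tau2:
            P_vec = np.concatenate([P_vec, P_sig])
            Q = np.zeros((I + 1, I + 1))
            Q[0, 0] = np.sum(u**3)
            Q[0, 1:] = Q[1:, 0] = c * u**3
            Q[1:, 1:] = np.diag(c**2 * u**3)
        else:
            P_vec = P_sig
            Q = np.diag(c**2 * u**3)

    theta_nat = np.concatenate([[tau2], [s2[0]] if shared_sigma2 else s2])
    if information == "observed":
        H = _observed_info(theta_nat, d, c, m, rss, shared_sigma2, free_tau2)
    elif information == "expected":
        H = _expected_info_one_stage(tau2, s2, c, m, shared_sigma2)
        if not free_tau2:
            H = H[1:, 1:]
    else:
        raise ValueError(f"unknown information type {information!r}")
    try:
        W = np.linalg.inv(H)
        if np.any(np.diag(W) < 0):
            raise np.linalg.LinAlgError("negative variance of variance estimates")
    except np.linalg.LinAlgError:
        logger.warning("observed information not positive definite; "
                       "using expected information instead")
        He = _expected_info_one_stage(tau2, s2, c, m, shared_sigma2)
        if not free_tau2:
            He = He[1:, 1:]
        W = np.linalg.inv(He)

    var_adj, df = _kr_scalar(Phi, np.asarray(P_vec), Q, W)

    fit = REMLFit(
        tau2_hat=tau2,
        beta_hat=beta,
        var_naive=Phi,
        var_adjusted=var_adj,
        df_kr=df,
        information=information,
        converged=bool(res.success),
        iterations=int(res.nit),
        loglik=-float(res.fun),
        procedure="one_stage",
        sigma2_hats=s2,
    )
    method = MethodInfo(
        model="V", procedure="one_stage", residual_variance="study_specific",
        correction="kenward_roger", information=information,
    )
    result = make_result(beta, var_adj, level, df, method, tau2_hat=tau2)
    return fit, result
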