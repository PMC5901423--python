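"""Expected values of the fixed-effect variance formulas.

Setting: I studies of common size n, a common true residual variance
sigma^2 and a common true effect.  Three variance estimators of the pooled
effect are compared through their expectations over repeated sampling:

* ``ols`` — the shared-variance estimator sigma2_hat/W_d with design weight
  W_d = sum n_t n_c / n; unbiased, expectation sigma^2 c / I exactly
  (c = 1/n_t + 1/n_c).
* ``asymptotic`` — the inverse-variance formula 1/W_hat with estimated
  weights 1/(c sigma2_hat_i).  Its expectation is
  (c sigma^2 / m) E[1 / sum_i 1/Q_i] with Q_i ~ chi2_m, m = n - 2, which is
  evaluated deterministically through the Laplace-transform identity
  E[1/S] = int_0^inf (E[exp(-t/Q)])^I dt (nested adaptive quadrature).
* ``small_sample`` — the delta-method-corrected formula.  No closed form for
  its expectation is available, so Monte Carlo is the primary method; the
  default estimator integrates the effect estimates out analytically
  conditional on the drawn weights (a Rao-Blackwellised estimator whose only
  noise comes from the variance draws), while ``estimator="full"`` simulates
  the effect estimates as well and, with ``sampler="ols"``, full per-study
  regressions.

Ratios of the two-stage expectations to the OLS expectation are the theory
curves: the asymptotic formula sits below 1 (it ignores weight estimation),
the small-sample formula above 1, both approaching 1 as n grows, with very
little dependence on I.  The ratios do not depend on sigma^2 (scale cancels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .errors import UnsupportedFormulaError
from .fixed import SMALL_SAMPLE_COEF, SMALL_SAMPLE_DF_OFFSET

__all__ = ["ExpectedVariance", "TheoryCurve", "expected_variance",
           "variance_ratio_curves", "DEFAULT_N_GRID"]

DEFAULT_N_GRID = tuple(range(4, 101, 2))
DEFAULT_REPS = 200_000


@dataclass(frozen=True)
class ExpectedVariance:
    value: float
    mc_se: float  # 0 for deterministic (closed-form) evaluations
    formula: str
    method: str


@dataclass(frozen=True)
class TheoryCurve:
    """Expected-variance ratio curves for a fixed study count I."""

    n_grid: np.ndarray
    I: int
    ratio_asymptotic: np.ndarray
    ratio_small_sample: np.ndarray
    sigma2: float
    mc_se_asymptotic: np.ndarray
    mc_se_small_sample: np.ndarray


def _arm_split(n: int) -> tuple[int, int]:
    n_t = n // 2
    return n_t, n - n_t


def _design_c(n: int) -> float:
    n_t, n_c = _arm_split(n)
    return 1.0 / n_t + 1.0 / n_c


# ---------------------------------------------------------------------------
# deterministic expectation of the asymptotic formula
# ---------------------------------------------------------------------------

def _log_laplace_inv_chi2(t: float, m: float) -> float:
    """log E[exp(-t/Q)] for Q ~ chi-square on m df.

    Evaluated in w = log q, where the exponent
    g(w) = -t e^-w - e^w/2 + (m/2) w is strictly concave, so a single
    Laplace window around the mode captures the integral.
    """
    if t == 0.0:
        return 0.0
    qstar = 0.5 * (m + math.sqrt(m * m + 8.0 * t))
    wstar = math.log(qstar)
    curv = t / qstar + qstar / 2.0  # -g''(wstar) > 0
    sig = 1.0 / math.sqrt(curv)
    lo = wstar - (15.0 * sig + 80.0 / m)
    hi = wstar + (15.0 * sig + 10.0)
    gstar = -t / qstar - qstar / 2.0 + 0.5 * m * wstar

    def integrand(w):
        return math.exp(-t * math.exp(-w) - 0.5 * math.exp(w) + 0.5 * m * w - gstar)

    val, _ = quad(
        integrand, lo, hi, epsabs=0.0, epsrel=1e-11, limit=200,
        points=[wstar - 2 * sig, wstar, wstar + 2 * sig],
    )
    if not val > 0.0:  # integrand underflowed everywhere off the peak
        val = sig * math.sqrt(2.0 * math.pi)  # Laplace approximation
    return gstar + math.log(val) - 0.5 * m * math.log(2.0) - math.lgamma(0.5 * m)


def _expect_inv_sum_inv_chi2(m: float, I: int, epsrel: float = 1e-9) -> float:
    """E[1 / sum_{i<=I} 1/Q_i], Q_i iid chi-square(m), via E[1/S]=int E[e^-tS] dt."""
    a = max(m - 2.0, 0.5) / I  # scale so the decay happens at u = O(1)

    def f(u):
        t = a * u * u
        return math.exp(I * _log_laplace_inv_chi2(t, m)) * 2.0 * a * u

    val, _ = quad(f, 0.0, np.inf, epsabs=0.0, epsrel=epsrel, limit=300)
    return val


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _draw_sigma2_hats(rng, reps, I, n, sigma2, sampler, df_offset):
    """Draws of the per-study residual-variance estimates, (reps, I)."""
    m = n - df_offset
    if m < 1:
        raise ValueError("no residual degrees of freedom")
    if sampler == "chi2":
        return sigma2 * rng.chisquare(m, size=(reps, I)) / m, None
    if sampler == "ols":
        # full per-study two-parameter regressions on simulated Gaussian data
        n_t, n_c = _arm_split(n)
        sd = math.sqrt(sigma2)
        yt = rng.normal(0.0, sd, size=(reps, I, n_t))
        yc = rng.normal(0.0, sd, size=(reps, I, n_c))
        rss = ((yt - yt.mean(axis=2, keepdims=True)) ** 2).sum(axis=2) + (
            (yc - yc.mean(axis=2, keepdims=True)) ** 2
        ).sum(axis=2)
        beta_hats = yt.mean(axis=2) - yc.mean(axis=2)
        return rss / (n - 2), beta_hats
    raise ValueError(f"unknown sampler {sampler!r}")


def expected_variance(
    formula: str,
    n: int,
    I: int,
    sigma2: float = 1.0,
    method: str = "closed_form",
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
    *,
    sampler: str = "chi2",
    estimator: str = "conditional",
    df_offset: int = 2,
) -> ExpectedVariance:
    """Expectation of a pooled-variance formula under the equal-n, equal-sigma2 model.

    ``df_offset`` sets the residual df (n - df_offset) of the simulated
    sigma2_hat draws; 2 matches the per-study two-parameter regression.
    """
    c = _design_c(n)
    m = n - df_offset
    if formula == "ols":
        if method == "closed_form":
            return ExpectedVariance(sigma2 * c / I, 0.0, formula, method)
        rng = np.random.default_rng(seed)
        s2h, bh = _draw_sigma2_hats(rng, reps, I, n, sigma2, sampler, df_offset)
        if bh is None:
            bh = rng.normal(0.0, math.sqrt(sigma2 * c), size=(reps, I))
        w_d = 1.0 / c  # equal per-study design weights n_t n_c / n
        W_d = I * w_d
        bbar = bh.mean(axis=1)
        rss = (n - 2) * s2h.sum(axis=1) + w_d * ((bh - bbar[:, None]) ** 2).sum(axis=1)
        vals = rss / (n * I - I - 1) / W_d
        return ExpectedVariance(
            float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(reps)),
            formula, method,
        )

    if formula == "asymptotic":
        if method == "closed_form":
            val = (c * sigma2 / m) * _expect_inv_sum_inv_chi2(m, I)
            return ExpectedVariance(float(val), 0.0, formula, method)
        rng = np.random.default_rng(seed)
        s2h, _ = _draw_sigma2_hats(rng, reps, I, n, sigma2, sampler, df_offset)
        vals = 1.0 / (1.0 / (c * s2h)).sum(axis=1)
        return ExpectedVariance(
            float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(reps)),
            formula, method,
        )

    if formula == "small_sample":
        if method == "closed_form":
            raise UnsupportedFormulaError(
                "no closed-form expectation for the small-sample formula; "
                "use method='monte_carlo'"
            )
        rng = np.random.default_rng(seed)
        s2h, bh = _draw_sigma2_hats(rng, reps, I, n, sigma2, sampler, df_offset)
        w = 1.0 / (c * s2h)
        W = w.sum(axis=1)
        dff = n - SMALL_SAMPLE_DF_OFFSET  # divisor of Var(sigma2_hat) in the formula
        if estimator == "conditional":
            # integrate the effect estimates out analytically given the weights
            sw2 = (w**2).sum(axis=1)
            e_dev2 = sigma2 * c * (1.0 - 2.0 * w / W[:, None] + (sw2 / W**2)[:, None])
            vals = 1.0 / W + (
                SMALL_SAMPLE_COEF * w**2 * e_dev2 / dff
            ).sum(axis=1) / W**2
        elif estimator == "full":
            if bh is None:
                bh = rng.normal(0.0, math.sqrt(sigma2 * c), size=(reps, I))
            bpool = (w * bh).sum(axis=1) / W
            dev2 = (bh - bpool[:, None]) ** 2
            vals = 1.0 / W + (
                SMALL_SAMPLE_COEF * w**2 * dev2 / dff
            ).sum(axis=1) / W**2
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        return ExpectedVariance(
            float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(reps)),
            formula, method,
        )

    raise ValueError(f"unknown formula {formula!r}")


def variance_ratio_curves(
    n_grid=DEFAULT_N_GRID,
    I_list=(2, 10, 40),
    sigma2: float = 1.0,
    method: str = "closed_form",
    reps: int = DEFAULT_REPS,
    seed: int | None = 0,
) -> list[TheoryCurve]:
    """Ratio of two-stage expected variances to the OLS expected variance.

    ``method="closed_form"`` uses the deterministic quadrature for the
    asymptotic formula (Monte Carlo, which is primary for the small-sample
    formula, is used there either way); ``method="monte_carlo"`` uses Monte
    Carlo for both.
    """
    n_grid = np.asarray(list(n_grid), dtype=int)
    if np.any(n_grid < 4):
        raise ValueError("per-study sizes must be >= 4")
    curves = []
    ss = np.random.SeedSequence(seed)
    for I in I_list:
        ra = np.empty(n_grid.size)
        rs = np.empty(n_grid.size)
        sa = np.zeros(n_grid.size)
        sm = np.zeros(n_grid.size)
        for k, n in enumerate(n_grid):
            denom = expected_variance("ols", int(n), I, sigma2).value
            child = ss.spawn(1)[0]
            ev_a = expected_variance(
                "asymptotic", int(n), I, sigma2,
                method=method, reps=reps,
                seed=np.random.default_rng(child) if method != "closed_form" else None,
            )
            ev_s = expected_variance(
                "small_sample", int(n), I, sigma2,
                method="monte_carlo", reps=reps,
                seed=np.random.default_rng(ss.spawn(1)[0]),
            )
            ra[k] = ev_a.value / denom
            rs[k] = ev_s.value / denom
            sa[k] = ev_a.mc_se / denom
            sm[k] = ev_s.mc_se / denom
        curves.append(
            TheoryCurve(
                n_grid=n_grid.copy(), I=int(I),
                ratio_asymptotic=ra, ratio_small_sample=rs,
                sigma2=sigma2, mc_se_asymptotic=sa, mc_se_small_sample=sm,
            )
        )
    return curves
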