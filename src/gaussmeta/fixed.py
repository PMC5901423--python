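"""Fixed-effect estimation of the overall treatment effect.

Covers the common-effect models: a single regression on all patients
(model I), study fixed intercepts with a common effect (model II, the
"fixed-effects meta-analysis") under either a shared or study-specific
residual variance, and per-study fixed effects (model IV).  Both one-stage
(patient-level weighted least squares) and two-stage (pool study estimates)
procedures are provided; with matching assumptions they return identical
estimates, which is the structural identity the test suite pins down.

Two variance estimators for the study-specific-variance estimator are
implemented: the asymptotic inverse-variance formula 1/W (which treats the
estimated residual variances as known), and a small-sample formula that
acknowledges the sampling noise of each sigma2_hat_i through the weights.
A second-order expansion around the true weights shows two effects of equal
size Delta = (2/W^2) sum_i w_i (1 - w_i/W) / (n_i - 2): estimating the
weights inflates the true variance of the pooled estimate by Delta, and
plugging estimated weights into 1/W biases that formula down by the same
Delta.  Estimating the per-study factor v_i (1 - w_i/W) by the observed
squared deviation (beta_hat_i - beta_hat)^2 therefore gives

    Var(beta_hat) ~= 1/W + sum_i 4 w_i^2 (beta_hat_i - beta_hat)^2
                                   / ((n_i - 2) W^2),

which is unbiased for the sampling variance of the pooled estimate to
second order and reduces to 1/W as every n_i grows.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .data import (
    NORMAL_DF,
    AggregateDataset,
    IPDDataset,
    MetaResult,
    MethodInfo,
    StudySummary,
    as_aggregate,
    make_result,
    summarize_studies,
)
from .errors import (
    DegenerateStudyError,
    MissingArmSizesError,
    UnsupportedModelError,
)

logger = logging.getLogger("gaussmeta")

#: Offset d in the divisor (n_i - d) of Var(sigma2_hat_i) = 2 sigma_i^4/(n_i - d)
#: used by the small-sample formula.  The per-study regression estimates an
#: intercept and a slope, so the residual df is n_i - 2.
SMALL_SAMPLE_DF_OFFSET = 2

#: Coefficient of the delta-method term: 2 for the weight-estimation
#: inflation of the true variance plus 2 for the equal-and-opposite plug-in
#: bias of 1/W (see the module docstring).
SMALL_SAMPLE_COEF = 4.0


def _weights_iv(agg: AggregateDataset) -> np.ndarray:
    v = agg.v
    if np.any(v <= 0):
        bad = agg.frame.loc[v <= 0, "study"].tolist()
        raise DegenerateStudyError(f"zero estimated variance for study(ies): {bad}")
    return 1.0 / v


def variance_asymptotic(summaries) -> float:
    """Asymptotic inverse-variance estimate 1/W, W = sum 1/v_i.

    Under balanced arms v_i = 4 sigma2_hat_i / n_i, recovering the printed
    shorthand.
    """
    agg = as_aggregate(summaries)
    return float(1.0 / _weights_iv(agg).sum())


def variance_small_sample(
    summaries, beta_hat: float, *, df_offset: int = SMALL_SAMPLE_DF_OFFSET
) -> float:
    """Small-sample variance: 1/W plus the estimated-weights correction.

    Requires study sample sizes; evaluated at plug-in sigma2_hat_i (through
    the weights) and the observed deviations beta_hat_i - beta_hat.
    Always >= the asymptotic value; equal for a single study.
    """
    agg = as_aggregate(summaries)
    n = agg.require_sizes()
    if np.any(n - df_offset < 1):
        raise DegenerateStudyError("a study has no residual degrees of freedom")
    w = _weights_iv(agg)
    W = w.sum()
    if agg.n_studies < 2:
        logger.warning(
            "small-sample correction with a single study is identically zero"
        )
    dev = agg.beta_hats - beta_hat
    corr = float(np.sum(SMALL_SAMPLE_COEF * w**2 * dev**2 / (n - df_offset)) / W**2)
    return float(1.0 / W + corr)


def pool_inverse_variance(
    summaries, level: float = 0.95, *, variance: str = "asymptotic"
) -> MetaResult:
    """Two-stage fixed-effect pooling with inverse-variance weights.

    ``variance`` selects the CI variance: "asymptotic" (default, the
    inverse-variance formula) or "small_sample" (adds the estimated-weights
    correction; requires sample sizes).
    """
    agg = as_aggregate(summaries)
    w = _weights_iv(agg)
    W = w.sum()
    beta = float(np.sum(w * agg.beta_hats) / W)
    if variance == "asymptotic":
        var = 1.0 / W
    elif variance == "small_sample":
        var = variance_small_sample(agg, beta)
    else:
        raise ValueError(f"unknown variance estimator {variance!r}")
    method = MethodInfo(
        model="II",
        procedure="two_stage",
        residual_variance="study_specific",
        notes=f"variance={variance}",
    )
    return make_result(beta, var, level, NORMAL_DF, method)


def _ols_from_summaries(summaries: list[StudySummary]):
    """Senn's exact recovery of the model-II OLS fit from stage-1 summaries."""
    if any(s.n_t == 0 or s.n_c == 0 for s in summaries):
        raise MissingArmSizesError("arm sizes required for common-variance pooling")
    w = np.array([s.n_t * s.n_c / s.n for s in summaries], dtype=float)
    b = np.array([s.beta_hat for s in summaries])
    W = w.sum()
    beta = float(np.sum(w * b) / W)
    N = sum(s.n for s in summaries)
    I = len(summaries)
    # joint residual SS = within-study SS + between-study slope lack of fit
    rss = sum(s.df_resid * s.sigma2_hat for s in summaries) + float(
        np.sum(w * (b - beta) ** 2)
    )
    df = N - I - 1
    if df < 1:
        raise DegenerateStudyError("no residual df for the shared-variance fit")
    sigma2 = rss / df
    return beta, sigma2 / W, sigma2, df, w


def pool_common_variance(
    summaries, level: float = 0.95, *, sigma2_pooling: str = "ols"
) -> MetaResult:
    """Two-stage pooling under a shared residual variance (sample-size weights).

    Weights are n_t*n_c/n_i (proportional to n_i under 1:1 allocation).  With
    ``sigma2_pooling="ols"`` (default) the shared variance is reconstructed
    from the summaries including the between-study slope lack of fit, so the
    result equals the one-stage OLS fit of model II exactly;
    ``sigma2_pooling="within"`` uses the df-weighted pool of the within-study
    residual variances instead (df N - 2I, no lack-of-fit term).
    """
    summaries = list(as_aggregate_summaries(summaries))
    beta, var, sigma2, df, w = _ols_from_summaries(summaries)
    if sigma2_pooling == "within":
        df = sum(s.df_resid for s in summaries)
        if df < 1:
            raise DegenerateStudyError("no within-study residual df")
        sigma2 = sum(s.df_resid * s.sigma2_hat for s in summaries) / df
        var = sigma2 / w.sum()
    elif sigma2_pooling != "ols":
        raise ValueError(f"unknown sigma2_pooling {sigma2_pooling!r}")
    method = MethodInfo(
        model="II", procedure="two_stage", residual_variance="shared",
        notes=f"sigma2_hat={sigma2!r}, sigma2_pooling={sigma2_pooling}",
    )
    return make_result(beta, var, level, float(df), method)


def as_aggregate_summaries(summaries):
    """Coerce IPD or a summary list to a list of StudySummary."""
    if isinstance(summaries, IPDDataset):
        return summarize_studies(summaries)
    if isinstance(summaries, AggregateDataset):
        df = summaries.frame
        needed = ["n", "nt", "nc", "sigma2"]
        if df[needed].isna().any().any():
            raise MissingArmSizesError(
                "common-variance pooling needs n, nt, nc and sigma2 per study"
            )
        return [
            StudySummary(
                study_id=r.study,
                n=int(r.n),
                n_t=int(r.nt),
                n_c=int(r.nc),
                beta_hat=float(r.beta),
                sigma2_hat=float(r.sigma2),
                v=float(r.se) ** 2,
            )
            for r in df.itertuples()
        ]
    return list(summaries)


def fit_one_stage(
    data: IPDDataset,
    model: str = "II",
    residual_variance: str = "shared",
    level: float = 0.95,
) -> MetaResult:
    """One-stage fixed-effect fit on patient-level data.

    model "I": y ~ 1 + x (single intercept, shared variance).
    model "II": y ~ study intercepts + x; ``residual_variance`` selects the
        shared-variance OLS fit or the study-specific weighted fit whose
        estimate and variance coincide with two-stage inverse-variance pooling.
    model "IV": y ~ study intercepts + per-study x terms; returns per-study
        effects only (no pooled beta).
    """
    if model not in {"I", "II", "IV"}:
        raise UnsupportedModelError(f"unknown fixed-effect model {model!r}")
    if model in {"I", "IV"} and residual_variance != "shared":
        raise UnsupportedModelError(
            f"model {model} is only defined with a shared residual variance"
        )

    labels, inv = np.unique(np.asarray(data.study, dtype=object), return_inverse=True)
    I = len(labels)
    N = data.n

    if model == "I":
        X = np.column_stack([np.ones(N), data.x])
        coef, rss, df = _lstsq_fit(X, data.y)
        XtX_inv = np.linalg.inv(X.T @ X)
        sigma2 = rss / df
        var = sigma2 * XtX_inv[1, 1]
        method = MethodInfo(model="I", procedure="one_stage", residual_variance="shared")
        return make_result(coef[1], var, level, float(df), method)

    # study-indicator design (one dummy per study, no global intercept)
    D = np.zeros((N, I))
    D[np.arange(N), inv] = 1.0

    if model == "IV":
        X = np.column_stack([D, D * data.x[:, None]])
        coef, rss, df = _lstsq_fit(X, data.y)
        sigma2 = rss / df
        per_study = {
            str(lab): float(coef[I + k]) for k, lab in enumerate(labels)
        }
        method = MethodInfo(
            model="IV", procedure="one_stage", residual_variance="shared",
            notes="per-study effects only; no pooled beta",
        )
        # no pooled beta: report NaN estimate with per-study effects attached
        from .data import MetaResult as _MR

        return _MR(
            beta_hat=float("nan"),
            var_hat=float(sigma2),
            ci_low=float("nan"),
            ci_high=float("nan"),
            level=level,
            df=float(df),
            method=method,
            per_study=per_study,
        )

    X = np.column_stack([D, data.x])
    if residual_variance == "shared":
        coef, rss, df = _lstsq_fit(X, data.y)
        sigma2 = rss / df
        XtX_inv = np.linalg.inv(X.T @ X)
        var = sigma2 * XtX_inv[I, I]
        method = MethodInfo(model="II", procedure="one_stage", residual_variance="shared")
        return make_result(coef[I], var, level, float(df), method)

    if residual_variance != "study_specific":
        raise UnsupportedModelError(
            f"unknown residual variance assumption {residual_variance!r}"
        )

    # study-specific variances: estimate each sigma2 within study (per-study
    # OLS residual mean square), then solve the weighted normal equations on
    # the full patient-level design with per-row precision 1/sigma2_hat_i.
    summaries = summarize_studies(data)
    sigma2_by_label = {s.study_id: s.sigma2_hat for s in summaries}
    sigma2_row = np.array([sigma2_by_label[lab] for lab in labels])[inv]
    if np.any(sigma2_row <= 0):
        bad = sorted({str(lab) for lab in np.asarray(data.study)[sigma2_row <= 0]})
        raise DegenerateStudyError(
            f"zero within-study residual variance for study(ies): {bad}"
        )
    wrow = 1.0 / sigma2_row
    XtW = X.T * wrow
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ data.y)
    cov = np.linalg.inv(A)  # weights are precisions, so no scale factor
    method = MethodInfo(
        model="II", procedure="one_stage", residual_variance="study_specific"
    )
    return make_result(coef[I], cov[I, I], level, NORMAL_DF, method)


def _lstsq_fit(X: np.ndarray, y: np.ndarray):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = y.size - rank
    if df < 1:
        raise DegenerateStudyError("no residual degrees of freedom in OLS fit")
    return coef, rss, df
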