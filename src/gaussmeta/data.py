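"""Domain types and I/O for individual-participant and aggregate meta-analysis data.

The patient-level container (:class:`IPDDataset`) holds one row per patient:
a study label, a continuous outcome ``y`` and a treatment indicator ``x``
recoded internally to -0.5/+0.5 so that, under 1:1 randomisation, the
intercept of a regression of ``y`` on ``x`` is the overall mean outcome and
the slope is the treatment effect.

Stage-1 ("two-stage") reductions live in :class:`StudySummary`: the
within-study mean difference, residual variance and its implied variance of
the estimate.  :class:`AggregateDataset` is the CSV-facing equivalent and
tolerates missing optional columns, so published estimate/SE tables can be
pooled without patient data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateStudyError,
    EmptyDataError,
    MissingArmSizesError,
    MissingColumnError,
    StudyValidationError,
    TreatmentCodingError,
)

logger = logging.getLogger("gaussmeta")

IPD_COLUMNS = ("study", "y", "x")
AGG_COLUMNS = ("study", "beta", "se", "n", "nt", "nc", "sigma2")
AGG_REQUIRED = ("study", "beta", "se")

#: Sentinel for "use normal quantiles" in confidence intervals.
NORMAL_DF = math.inf


@dataclass(frozen=True)
class IPDDataset:
    """Validated patient-level data for a meta-analysis.

    Attributes
    ----------
    study : np.ndarray
        Study label per row (object/str array).
    y : np.ndarray
        Continuous outcome per row.
    x : np.ndarray
        Treatment indicator per row, coded -0.5 (control) / +0.5 (treated).
    """

    study: np.ndarray
    y: np.ndarray
    x: np.ndarray

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    @property
    def study_ids(self) -> list:
        seen: dict = {}
        for s in self.study:
            seen.setdefault(s, None)
        return list(seen)

    @property
    def n(self) -> int:
        return self.y.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"study": self.study, "y": self.y, "x": self.x})

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        *,
        strict: bool = True,
        columns: Mapping[str, str] | None = None,
    ) -> "IPDDataset":
        """Validate a raw table and recode treatment to -0.5/+0.5.

        Parameters
        ----------
        df : DataFrame with (mapped) columns study, y, x.
        strict : bool
            If True (default) a study with an empty arm raises
            :class:`StudyValidationError`; if False such studies are dropped
            with a logged warning.
        columns : optional mapping from canonical names (study, y, x) to the
            column names actually present in ``df``.
        """
        colmap = {c: c for c in IPD_COLUMNS}
        if columns:
            colmap.update(columns)
        missing = [colmap[c] for c in IPD_COLUMNS if colmap[c] not in df.columns]
        if missing:
            raise MissingColumnError(f"missing required column(s): {missing}")
        if len(df) == 0:
            raise EmptyDataError("IPD table contains no rows")

        study = df[colmap["study"]].to_numpy()
        y = pd.to_numeric(df[colmap["y"]], errors="coerce").to_numpy(dtype=float)
        x_raw = df[colmap["x"]].to_numpy()

        keep = ~(np.isnan(y) | pd.isna(x_raw))
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("dropping %d rows with missing y or x", n_dropped)
            study, y, x_raw = study[keep], y[keep], x_raw[keep]
        if y.size == 0:
            raise EmptyDataError("IPD table contains no complete rows")

        x = _recode_treatment(x_raw)

        # per-study arm counts
        bad = []
        for s in pd.unique(study):
            xs = x[study == s]
            if not ((xs > 0).any() and (xs < 0).any()):
                bad.append(s)
        if bad:
            if strict:
                raise StudyValidationError(
                    f"study(ies) with an empty treatment or control arm: {bad}"
                )
            logger.warning("dropping studies with an empty arm: %s", bad)
            mask = ~np.isin(study, bad)
            study, y, x = study[mask], y[mask], x[mask]
            if y.size == 0:
                raise EmptyDataError("no studies left after dropping invalid ones")

        return cls(study=study, y=np.asarray(y, float), x=x)


def _recode_treatment(x_raw: np.ndarray) -> np.ndarray:
    """Map any two-level coding onto -0.5/+0.5.

    The numerically (or, for strings, lexicographically) larger level becomes
    the treated arm (+0.5); the rule is deterministic and logged.
    """
    levels = pd.unique(x_raw)
    if len(levels) != 2:
        raise TreatmentCodingError(
            f"treatment must have exactly 2 levels, found {len(levels)}: {levels!r}"
        )
    try:
        as_num = np.asarray(levels, dtype=float)
        order = np.argsort(as_num)
    except (TypeError, ValueError):
        order = np.argsort(np.asarray(levels, dtype=str))
    control, treated = levels[order[0]], levels[order[1]]
    logger.info("treatment recoded: %r -> -0.5 (control), %r -> +0.5 (treated)",
                control, treated)
    x = np.where(np.asarray(x_raw == treated), 0.5, -0.5)
    return x.astype(float)


@dataclass(frozen=True)
class StudySummary:
    """Stage-1 results for a single study.

    ``beta_hat`` is the mean difference treated - control from the within-study
    regression of y on x (with intercept); ``sigma2_hat`` the residual mean
    square on ``df_resid = n - 2`` degrees of freedom; ``v`` the estimated
    variance of ``beta_hat``, sigma2_hat * (1/n_t + 1/n_c).
    """

    study_id: object
    n: int
    n_t: int
    n_c: int
    beta_hat: float
    sigma2_hat: float
    v: float

    @property
    def df_resid(self) -> int:
        return self.n - 2

    @property
    def c(self) -> float:
        """Design constant 1/n_t + 1/n_c (equals 4/n under balance)."""
        return 1.0 / self.n_t + 1.0 / self.n_c

    @property
    def se(self) -> float:
        return math.sqrt(self.v)


def summarize_studies(data: IPDDataset) -> list[StudySummary]:
    """Per-study OLS of y on x with intercept (the two-stage first stage).

    Equivalent to a two-sample comparison within each study: the slope is the
    difference in arm means, the residual variance is the pooled within-arm
    mean square on n_i - 2 df.
    """
    labels, inv = np.unique(np.asarray(data.study, dtype=object), return_inverse=True)
    treated = data.x > 0
    out: list[StudySummary] = []
    nt = np.bincount(inv, weights=treated).astype(int)
    nc = np.bincount(inv, weights=~treated).astype(int)
    n = nt + nc
    if np.any(n <= 2):
        bad = labels[n <= 2]
        raise DegenerateStudyError(
            f"study(ies) with n <= 2 have zero residual df: {list(bad)}"
        )
    sum_t = np.bincount(inv, weights=np.where(treated, data.y, 0.0))
    sum_c = np.bincount(inv, weights=np.where(treated, 0.0, data.y))
    mean_t, mean_c = sum_t / nt, sum_c / nc
    sumsq = np.bincount(inv, weights=data.y**2)
    rss = sumsq - nt * mean_t**2 - nc * mean_c**2
    rss = np.maximum(rss, 0.0)  # guard tiny negative round-off
    sigma2 = rss / (n - 2)
    c = 1.0 / nt + 1.0 / nc
    beta = mean_t - mean_c
    for k, lab in enumerate(labels):
        out.append(
            StudySummary(
                study_id=lab,
                n=int(n[k]),
                n_t=int(nt[k]),
                n_c=int(nc[k]),
                beta_hat=float(beta[k]),
                sigma2_hat=float(sigma2[k]),
                v=float(sigma2[k] * c[k]),
            )
        )
    # preserve first-appearance order of studies in the dataset
    first_pos = {lab: i for i, lab in enumerate(data.study_ids)}
    out.sort(key=lambda s: first_pos.get(s.study_id, len(first_pos)))
    return out


@dataclass(frozen=True)
class AggregateDataset:
    """Study-level estimates with standard errors (stage-2 input).

    Only study labels, estimates and standard errors are mandatory; sample
    sizes, arm sizes and residual variances are carried when available and
    required by downstream small-sample methods.
    """

    frame: pd.DataFrame  # columns AGG_COLUMNS; optional ones may hold NaN

    def __post_init__(self):
        df = self.frame
        missing = [c for c in AGG_REQUIRED if c not in df.columns]
        if missing:
            raise MissingColumnError(f"aggregate data missing column(s): {missing}")
        if len(df) == 0:
            raise EmptyDataError("aggregate table contains no rows")
        se = df["se"].to_numpy(dtype=float)
        if np.any(~(se > 0)):
            bad = df.loc[~(se > 0), "study"].tolist()
            raise DegenerateStudyError(f"non-positive standard error for: {bad}")
        if {"n", "nt", "nc"} <= set(df.columns):
            sub = df.dropna(subset=["n", "nt", "nc"])
            if len(sub) and not np.allclose(sub["nt"] + sub["nc"], sub["n"]):
                raise StudyValidationError("arm sizes do not add up to n")

    @property
    def n_studies(self) -> int:
        return len(self.frame)

    @property
    def beta_hats(self) -> np.ndarray:
        return self.frame["beta"].to_numpy(dtype=float)

    @property
    def v(self) -> np.ndarray:
        return self.frame["se"].to_numpy(dtype=float) ** 2

    def require_sizes(self) -> np.ndarray:
        if "n" not in self.frame.columns or self.frame["n"].isna().any():
            raise MissingArmSizesError(
                "study sample sizes are required for this method but are "
                "absent from the aggregate data"
            )
        return self.frame["n"].to_numpy(dtype=float)

    @classmethod
    def from_summaries(cls, summaries: Sequence[StudySummary]) -> "AggregateDataset":
        rows = [
            {
                "study": s.study_id,
                "beta": s.beta_hat,
                "se": s.se,
                "n": s.n,
                "nt": s.n_t,
                "nc": s.n_c,
                "sigma2": s.sigma2_hat,
            }
            for s in summaries
        ]
        return cls(pd.DataFrame(rows, columns=list(AGG_COLUMNS)))


@dataclass(frozen=True)
class MethodInfo:
    """Metadata identifying exactly which model and procedure produced a result."""

    model: str  # "I" | "II" | "IV" | "V"
    procedure: str  # "one_stage" | "two_stage"
    residual_variance: str  # "shared" | "study_specific"
    correction: str = "none"  # "none" | "kenward_roger"
    information: str = "expected"  # "expected" | "observed"
    notes: str = ""


@dataclass(frozen=True)
class MetaResult:
    """A pooled treatment-effect estimate with its uncertainty.

    ``df`` is the degrees of freedom used for the CI; ``math.inf`` means
    normal quantiles.  ``tau2_hat`` is present only for random-effects fits.
    """

    beta_hat: float
    var_hat: float
    ci_low: float
    ci_high: float
    level: float
    df: float
    method: MethodInfo
    tau2_hat: float | None = None
    per_study: dict = field(default_factory=dict)

    @property
    def se(self) -> float:
        return math.sqrt(self.var_hat)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["se"] = self.se
        return d


def _quantile(level: float, df: float) -> float:
    from scipy import stats

    alpha = 1.0 - level
    if math.isinf(df):
        return float(stats.norm.ppf(1 - alpha / 2))
    return float(stats.t.ppf(1 - alpha / 2, df))


def make_result(beta_hat, var_hat, level, df, method, tau2_hat=None, **extra) -> MetaResult:
    if not var_hat > 0:
        raise DegenerateStudyError(f"pooled variance must be positive, got {var_hat}")
    q = _quantile(level, df)
    se = math.sqrt(var_hat)
    return MetaResult(
        beta_hat=float(beta_hat),
        var_hat=float(var_hat),
        ci_low=float(beta_hat - q * se),
        ci_high=float(beta_hat + q * se),
        level=level,
        df=df,
        method=method,
        tau2_hat=tau2_hat,
        per_study=extra.get("per_study", {}),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_ipd_csv(
    path,
    *,
    columns: Mapping[str, str] | None = None,
    strict: bool = True,
) -> IPDDataset:
    """Read patient-level data from CSV (default columns ``study,y,x``)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyDataError(f"{path}: empty file") from exc
    return IPDDataset.from_frame(df, strict=strict, columns=columns)


def write_ipd_csv(data: IPDDataset, path) -> None:
    data.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_aggregate_csv(summaries, path) -> None:
    """Write stage-1 summaries (or an AggregateDataset) to CSV losslessly."""
    if isinstance(summaries, AggregateDataset):
        agg = summaries
    else:
        agg = AggregateDataset.from_summaries(summaries)
    agg.frame.to_csv(path, index=False, float_format="%.17g")


def read_aggregate_csv(path) -> AggregateDataset:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyDataError(f"{path}: empty file") from exc
    for c in AGG_COLUMNS:
        if c not in df.columns and c not in AGG_REQUIRED:
            df[c] = np.nan
    return AggregateDataset(df[list(AGG_COLUMNS)])


def as_aggregate(data) -> AggregateDataset:
    """Coerce IPD, summaries or aggregate data to an AggregateDataset."""
    if isinstance(data, AggregateDataset):
        return data
    if isinstance(data, IPDDataset):
        return AggregateDataset.from_summaries(summarize_studies(data))
    return AggregateDataset.from_summaries(list(data))
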