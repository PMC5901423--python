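"""Synthetic IPD meta-analysis datasets.

The generator emulates a meta-analysis of 1:1-randomised trials with a
Gaussian outcome: study sizes are log-normal (rounded, floored at 20),
per-study residual variances are scaled inverse-chi-square draws with mean
close to 1, study intercepts are fixed at 0, and treatment effects are
study-specific Gaussian deviations around the overall effect
(beta_i = beta + b_i, b_i ~ N(0, tau2)).  Defaults match the study sizes of
published hepato-biliary trial corpora (meanlog 3.798, sdlog 1.104), giving
a right-skewed size distribution with mean about 82 patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import IPDDataset

__all__ = [
    "DGMConfig",
    "MetaDatasetBundle",
    "draw_study_sizes",
    "draw_residual_variances",
    "simulate_meta_ipd",
    "make_toy_fixture",
]


@dataclass(frozen=True)
class DGMConfig:
    """Configuration of the data-generating mechanism.

    Parameters
    ----------
    I : number of studies (>= 2).
    beta : true overall treatment effect (outcome units).
    tau2 : between-study variance of the treatment effects (>= 0).
    meanlog, sdlog : parameters of the log-normal study-size distribution.
    size_floor : minimum study size after rounding (>= 4).
    resid_df : df of the chi-square in the residual-variance draw (> 2).
    resid_scale : numerator of the scaled inverse-chi-square draw, so that
        sigma_i^2 = resid_scale / chi2(resid_df); with both at 50 the mean
        residual variance is 50/48, close to 1.
    seed : RNG seed; all draws are a pure function of (config, seed).
    """

    I: int = 10
    beta: float = 0.0
    tau2: float = 1.0
    meanlog: float = 3.798
    sdlog: float = 1.104
    size_floor: int = 20
    resid_df: float = 50.0
    resid_scale: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.I < 2:
            raise ValueError("I must be >= 2")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.size_floor < 4:
            raise ValueError("size_floor must be >= 4")
        if self.resid_df <= 2:
            raise ValueError("resid_df must be > 2 for finite mean variance")

    def with_seed(self, seed: int) -> "DGMConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class MetaDatasetBundle:
    """A simulated dataset together with the truths that generated it."""

    ipd: IPDDataset
    beta_i: np.ndarray  # true per-study effects beta + b_i
    sigma2_i: np.ndarray  # true per-study residual variances
    sizes: np.ndarray  # per-study n_i
    config: DGMConfig


def draw_study_sizes(I, meanlog=3.798, sdlog=1.104, size_floor=20, rng=None):
    """n_i = round(exp(Z)), Z ~ N(meanlog, sdlog^2), floored at ``size_floor``.

    Rounding happens first; any rounded value below the floor is set to it.
    """
    rng = np.random.default_rng(rng)
    raw = np.exp(rng.normal(meanlog, sdlog, size=int(I)))
    sizes = np.rint(raw).astype(int)
    return np.maximum(sizes, int(size_floor))


def draw_residual_variances(I, resid_df=50.0, resid_scale=50.0, rng=None):
    """sigma_i^2 = resid_scale / Q_i with Q_i ~ chi-square(resid_df), iid."""
    rng = np.random.default_rng(rng)
    q = rng.chisquare(resid_df, size=int(I))
    return resid_scale / q


def _arm_sizes(n: int) -> tuple[int, int]:
    # 1:1 allocation; the control arm receives the extra patient when n is odd
    n_t = n // 2
    return n_t, n - n_t


def simulate_meta_ipd(config: DGMConfig) -> MetaDatasetBundle:
    """Simulate one IPD meta-analysis under the random-effects mechanism.

    y_ij = beta_i * x_ij + eps_ij with beta_i = beta + b_i, b_i ~ N(0, tau2),
    eps_ij ~ N(0, sigma_i^2), x_ij = +/-0.5 and all study intercepts 0.
    """
    rng = np.random.default_rng(config.seed)
    sizes = draw_study_sizes(
        config.I, config.meanlog, config.sdlog, config.size_floor, rng
    )
    sigma2 = draw_residual_variances(config.I, config.resid_df, config.resid_scale, rng)
    beta_i = config.beta + rng.normal(0.0, np.sqrt(config.tau2), size=config.I)

    total = int(sizes.sum())
    study = np.empty(total, dtype=object)
    y = np.empty(total, dtype=float)
    x = np.empty(total, dtype=float)
    pos = 0
    for i in range(config.I):
        n = int(sizes[i])
        n_t, n_c = _arm_sizes(n)
        xi = np.concatenate([np.full(n_t, 0.5), np.full(n_c, -0.5)])
        eps = rng.normal(0.0, np.sqrt(sigma2[i]), size=n)
        study[pos : pos + n] = f"study_{i + 1:03d}"
        x[pos : pos + n] = xi
        y[pos : pos + n] = beta_i[i] * xi + eps
        pos += n

    ipd = IPDDataset(study=study, y=y, x=x)
    return MetaDatasetBundle(
        ipd=ipd, beta_i=beta_i, sigma2_i=sigma2, sizes=sizes, config=config
    )


@dataclass(frozen=True)
class ToyStudySpec:
    n: int
    beta: float
    sigma2: float


def make_toy_fixture(
    studies: Sequence[tuple[int, float, float]] | Sequence[ToyStudySpec],
    seed: int = 0,
) -> MetaDatasetBundle:
    """Deterministic small dataset from explicit per-study (n, beta_i, sigma2_i).

    Useful for unit tests: the requested truths are echoed exactly in the
    bundle, and regenerating with the same spec and seed is bitwise identical.
    """
    specs = [s if isinstance(s, ToyStudySpec) else ToyStudySpec(*s) for s in studies]
    for s in specs:
        if s.n < 4:
            raise ValueError(f"toy studies need n >= 4, got {s.n}")
        if s.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    study, y, x = [], [], []
    for i, s in enumerate(specs):
        n_t, n_c = _arm_sizes(s.n)
        xi = np.concatenate([np.full(n_t, 0.5), np.full(n_c, -0.5)])
        eps = rng.normal(0.0, np.sqrt(s.sigma2), size=s.n) if s.sigma2 > 0 else np.zeros(s.n)
        study.append(np.full(s.n, f"study_{i + 1:03d}", dtype=object))
        x.append(xi)
        y.append(s.beta * xi + eps)
    ipd = IPDDataset(
        study=np.concatenate(study), y=np.concatenate(y), x=np.concatenate(x)
    )
    cfg = DGMConfig(I=max(len(specs), 2), seed=seed)
    return MetaDatasetBundle(
        ipd=ipd,
        beta_i=np.array([s.beta for s in specs]),
        sigma2_i=np.array([s.sigma2 for s in specs]),
        sizes=np.array([s.n for s in specs]),
        config=cfg,
    )
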