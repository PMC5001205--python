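"""Mean-variance models for single-cell RNA-seq gene expression.

The gene expression variation model (GEVM) describes the per-gene variance
across a cell population as a quadratic function of the mean,

    sigma^2 = beta * mu + alpha * mu^2,

where ``alpha`` is the negative-binomial dispersion (the reciprocal of the NB
size parameter, setting the high-expression CV asymptote ``sqrt(alpha)``) and
``beta`` aggregates multiplicative technical noise dominating at low
expression (``beta = 1`` recovers Poisson behaviour there).  On the log-log
CV-mean plane the model is the curve

    log10(CV) = 1/2 * log10(beta / mu + alpha).

A simpler comparison noise model, ``log10(CV) = log10(mu**gamma + delta)``,
is also provided; it is used only as a fitting baseline.

All functions accept scalars or numpy arrays and are pure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "GEVMParams",
    "NoiseModelParams",
    "NBParams",
    "PoissonParams",
    "model_variance",
    "model_log10cv",
    "nb_from_mean",
    "noise_model_log10cv",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class GEVMParams:
    """Parameter pair of the quadratic variance model sigma^2 = beta*mu + alpha*mu^2.

    alpha : NB dispersion, dimensionless, >= 0 (alpha = 0 is the Poisson limit).
    beta  : technical-noise multiplier, dimensionless, > 0.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")


@dataclass(frozen=True)
class NoiseModelParams:
    """Parameters of the comparison noise model log10(CV) = log10(mu**gamma + delta)."""

    gamma: float
    delta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and np.isfinite(self.delta)):
            raise ValueError("gamma and delta must be finite")


@dataclass(frozen=True)
class NBParams:
    """Negative-binomial (size, prob) pair with prob = mu/sigma^2, size = mu^2/(sigma^2 - mu)."""

    size: float
    prob: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.size) or self.size <= 0:
            raise ValueError(f"NB size must be > 0, got {self.size}")
        if not (0 < self.prob <= 1):
            raise ValueError(f"NB prob must be in (0, 1], got {self.prob}")

    @property
    def mean(self) -> float:
        return self.size * (1.0 - self.prob) / self.prob

    @property
    def variance(self) -> float:
        return self.mean / self.prob


@dataclass(frozen=True)
class PoissonParams:
    """Poisson fallback for means where the model variance does not exceed the mean."""

    rate: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"Poisson rate must be > 0, got {self.rate}")


def _check_positive_mu(mu: ArrayLike) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
        raise ValueError("mean expression mu must be finite and > 0")
    return mu


def model_variance(mu: ArrayLike, params: GEVMParams) -> ArrayLike:
    """Model variance beta*mu + alpha*mu^2; strictly increasing in mu."""
    mu = _check_positive_mu(mu)
    out = params.beta * mu + params.alpha * mu**2
    return out if out.ndim else float(out)


def model_log10cv(mu: ArrayLike, params: GEVMParams) -> ArrayLike:
    """Model curve log10(CV) = 1/2 * log10(beta/mu + alpha).

    Tends to -1/2*log10(mu) on the Poisson line (alpha=0, beta=1) and to the
    constant 1/2*log10(alpha) as mu -> infinity when alpha > 0.
    """
    mu = _check_positive_mu(mu)
    out = 0.5 * np.log10(params.beta / mu + params.alpha)
    return out if out.ndim else float(out)


def nb_from_mean(mu: float, params: GEVMParams) -> Union[NBParams, PoissonParams]:
    """Map a mean to the NB (size, prob) implied by the model variance.

    size = mu / (beta - 1 + alpha*mu), prob = 1 / (beta + alpha*mu).  When the
    model variance does not exceed the mean (beta <= 1 and alpha*mu <= 1-beta)
    the NB size is undefined or negative, so the Poisson limit with rate mu is
    returned instead.
    """
    mu = float(_check_positive_mu(mu))
    var = params.beta * mu + params.alpha * mu**2
    if var <= mu:
        return PoissonParams(rate=mu)
    return NBParams(
        size=mu / (params.beta - 1.0 + params.alpha * mu),
        prob=1.0 / (params.beta + params.alpha * mu),
    )


def noise_model_log10cv(mu: ArrayLike, params: NoiseModelParams) -> ArrayLike:
    """Comparison noise model log10(CV) = log10(mu**gamma + delta)."""
    mu = _check_positive_mu(mu)
    inner = mu**params.gamma + params.delta
    if np.any(inner <= 0):
        raise ValueError("mu**gamma + delta must be > 0 on the whole input")
    out = np.log10(inner)
    return out if out.ndim else float(out)
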