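"""Negative-binomial likelihood machinery and dispersion estimation.

The negative binomial is parametrized by its mean ``mu`` and the *inverse
dispersion* ``theta`` (variance ``mu + mu**2 / theta``; smaller theta means
more cell-to-cell heterogeneity).  Per-gene theta is estimated by a
regularized Fisher-scoring iteration in which a penalty ``lambda / theta**2``
shrinks small theta estimates upward, so that baseline biological variability
is learned without deflating theta because of cluster structure or excess
zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, digamma, polygamma

__all__ = [
    "FisherScoringConfig",
    "ThetaEstimate",
    "nb_logpmf",
    "nb_score",
    "nb_fisher_info",
    "fisher_scoring_update",
    "estimate_theta",
    "moment_theta",
    "sample_nb",
]


def sample_nb(mu, theta, rng: np.random.Generator, method: str = "direct"):
    """Draw NB(mu, theta) counts, elementwise over broadcast mu/theta.

    ``direct`` uses the NB sampler with success probability theta/(theta+mu);
    ``gamma_poisson`` draws a gamma(shape=theta, mean=mu) rate and then a
    Poisson count — the two are equivalent in distribution.
    """
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    _check_mu_theta(np.maximum(mu, np.finfo(float).tiny), theta)
    if method == "direct":
        return rng.negative_binomial(theta, theta / (theta + mu))
    if method == "gamma_poisson":
        rate = rng.gamma(shape=theta, scale=mu / theta)
        return rng.poisson(rate)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class FisherScoringConfig:
    """Settings for the regularized Fisher-scoring iteration.

    lambda_reg is the regularization strength (0 = plain maximum likelihood);
    iteration stops once the relative change of theta drops below ``tol`` or
    ``max_iter`` updates have been taken.  Estimates are clipped into
    ``theta_bounds`` after every update.
    """

    lambda_reg: float = 5.0
    max_iter: int = 100
    tol: float = 1e-6
    theta_bounds: tuple[float, float] = (0.01, 1000.0)

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        lo, hi = self.theta_bounds
        if not (0 < lo < hi):
            raise ValueError("theta_bounds must satisfy 0 < low < high")


@dataclass(frozen=True)
class ThetaEstimate:
    theta: float
    converged: bool
    n_iter: int


def _check_mu_theta(mu, theta) -> None:
    if np.any(np.asarray(mu) <= 0):
        raise ValueError("mu must be positive")
    if np.any(np.asarray(theta) <= 0):
        raise ValueError("theta must be positive")


def nb_logpmf(v, mu, theta):
    """Elementwise log NB(mu, theta) pmf at counts ``v``.

    Computed through log-gamma so non-integer theta is exact:
    ``lgamma(v+theta) - lgamma(v+1) - lgamma(theta)
    + theta*log(theta/(theta+mu)) + v*log(mu/(theta+mu))``.
    """
    v = np.asarray(v)
    if np.any(v < 0) or not np.issubdtype(np.asarray(v).dtype, np.number):
        raise ValueError("v must be nonnegative")
    _check_mu_theta(mu, theta)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return (
        gammaln(v + theta)
        - gammaln(v + 1.0)
        - gammaln(theta)
        + theta * np.log(theta / (theta + mu))
        + v * np.log(mu / (theta + mu))
    )


def nb_score(theta: float, x, mu) -> float:
    """Score V(theta): derivative of the NB log-likelihood in theta.

    For observations x_i with means mu_i,
    ``V = sum_i psi(x_i+theta) - psi(theta) + log(theta/(theta+mu_i))
    + 1 - (x_i+theta)/(theta+mu_i)``.
    """
    x = np.asarray(x, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), x.shape)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    _check_mu_theta(mu, theta)
    return float(
        np.sum(
            digamma(x + theta)
            - digamma(theta)
            + np.log(theta / (theta + mu))
            + 1.0
            - (x + theta) / (theta + mu)
        )
    )


def nb_fisher_info(theta: float, x, mu) -> float:
    """Observed information -d2l/dtheta2 of the NB log-likelihood.

    Uses trigamma terms:
    ``-sum_i [ psi'(x_i+theta) - psi'(theta) + 1/theta - 2/(theta+mu_i)
    + (x_i+theta)/(theta+mu_i)**2 ]``.
    """
    x = np.asarray(x, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), x.shape)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    _check_mu_theta(mu, theta)
    d2 = np.sum(
        polygamma(1, x + theta)
        - polygamma(1, theta)
        + 1.0 / theta
        - 2.0 / (theta + mu)
        + (x + theta) / (theta + mu) ** 2
    )
    info = float(-d2)
    if not np.isfinite(info):
        raise FloatingPointError("non-finite Fisher information")
    return info


def fisher_scoring_update(
    theta_k: float,
    x,
    mu,
    lambda_reg: float = 0.0,
    theta_bounds: tuple[float, float] = (0.01, 1000.0),
) -> float:
    """One regularized Fisher-scoring step.

    theta_{k+1} = theta_k + (V(theta_k) + lambda*2/theta_k^3)
                          / (I(theta_k) + lambda*6/theta_k^4),
    clipped into ``theta_bounds``.  Smaller theta receives a larger penalty
    contribution, pushing the estimate upward.  If the denominator is not
    positive the step is halved against a unit curvature (with a warning).
    """
    if theta_k <= 0:
        raise ValueError("theta_k must be positive")
    num = nb_score(theta_k, x, mu) + lambda_reg * 2.0 / theta_k**3
    den = nb_fisher_info(theta_k, x, mu) + lambda_reg * 6.0 / theta_k**4
    if den <= 0:
        warnings.warn(
            "non-positive curvature in Fisher scoring; taking a damped step",
            RuntimeWarning,
            stacklevel=2,
        )
        step = 0.5 * np.sign(num) * min(abs(num), theta_k / 2.0)
    else:
        step = num / den
    return float(np.clip(theta_k + step, *theta_bounds))


def moment_theta(x, theta_bounds: tuple[float, float] = (0.01, 1000.0)) -> float:
    """Method-of-moments start: mean^2 / (var - mean), clipped.

    Genes whose variance does not exceed their mean (Poisson-like or
    degenerate) receive the upper bound.
    """
    x = np.asarray(x, dtype=float)
    m, v = x.mean(), x.var()
    if v <= m or m == 0:
        return theta_bounds[1]
    return float(np.clip(m * m / (v - m), *theta_bounds))


def estimate_theta(x, mu, cfg: FisherScoringConfig | None = None) -> ThetaEstimate:
    """Iterate Fisher scoring from a method-of-moments start.

    Returns the estimate together with a convergence flag; an all-zero gene
    (no information about overdispersion) gets the upper bound with a warning.
    """
    if cfg is None:
        cfg = FisherScoringConfig()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("x must be nonempty")
    if np.all(x == 0):
        warnings.warn("all-zero gene: theta set to upper bound", RuntimeWarning, stacklevel=2)
        return ThetaEstimate(cfg.theta_bounds[1], True, 0)
    theta = moment_theta(x, cfg.theta_bounds)
    for it in range(1, cfg.max_iter + 1):
        theta_new = fisher_scoring_update(
            theta, x, mu, cfg.lambda_reg, cfg.theta_bounds
        )
        rel = abs(theta_new - theta) / theta
        theta = theta_new
        if rel < cfg.tol:
            return ThetaEstimate(theta, True, it)
    warnings.warn("Fisher scoring did not converge", RuntimeWarning, stacklevel=2)
    return ThetaEstimate(theta, False, cfg.max_iter)
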