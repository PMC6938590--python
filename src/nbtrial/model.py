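"""Mean-dispersion negative binomial (NB2) likelihood and flat-prior posterior.

The outcome model is

    y_i ~ NB2(mu_i, phi),   log mu_i = x_i' beta,

where NB2 has mean mu and variance mu + mu^2/phi; phi > 0 is the dispersion
(Poisson in the phi -> infinity limit).  Priors are improper flat on every
regression coefficient and flat on phi over the positive reals, with optional
finite bounds.  All computation is in log space via log-gamma; no pmf is ever
formed by multiplying probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, digamma

from .data import DesignMatrix


@dataclass
class ParameterVector:
    """Regression coefficients plus dispersion, aligned to a design's column map.

    A non-positive ``phi`` is representable (so a sampler or optimizer can
    evaluate arbitrary points) but lies off the prior support: the posterior
    there is ``-inf`` and the likelihood refuses it.
    """

    beta: np.ndarray
    phi: float
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 1:
            raise ValueError("beta must be a 1-D vector")


@dataclass
class PriorSpec:
    """Flat (improper) priors, optionally truncated to finite boxes.

    ``beta_bounds`` is a (low, high) pair applied to every coefficient;
    ``phi_bounds`` truncates the dispersion.  Both default to None, i.e. the
    fully improper flat prior.
    """

    beta_bounds: tuple[float, float] | None = None
    phi_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for b in (self.beta_bounds, self.phi_bounds):
            if b is not None:
                lo, hi = b
                if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                    raise ValueError(f"bounds must be finite and ordered, got {b}")

    def in_support(self, params: ParameterVector) -> bool:
        if params.phi <= 0:
            return False
        if self.beta_bounds is not None:
            lo, hi = self.beta_bounds
            if (params.beta < lo).any() or (params.beta > hi).any():
                return False
        if self.phi_bounds is not None:
            lo, hi = self.phi_bounds
            if not (lo <= params.phi <= hi):
                return False
        return True


def nb2_log_pmf(y, mu, phi):
    """Log pmf of the mean-dispersion negative binomial.

    ``log C(y+phi-1, y) + phi*log(phi/(phi+mu)) + y*log(mu/(phi+mu))``,
    evaluated with log-gamma so large counts cannot overflow.  Broadcasts
    over array arguments.

    Parameters
    ----------
    y : int or array
        Non-negative integer count(s).
    mu : float or array
        Positive mean(s).
    phi : float or array
        Positive dispersion(s); variance is ``mu + mu**2/phi``.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if (np.asarray(y) < 0).any() or not np.array_equal(y, np.floor(y)):
        raise ValueError("y must be non-negative integer(s)")
    if (mu <= 0).any() or (phi <= 0).any():
        raise ValueError("mu and phi must be positive")
    y = y.astype(float)
    log_phi_term = np.log(phi) - np.log(phi + mu)
    log_mu_term = np.log(mu) - np.log(phi + mu)
    out = gammaln(y + phi) - gammaln(phi) - gammaln(y + 1) + phi * log_phi_term + y * log_mu_term
    return out if out.shape else float(out)


def _loglik_raw(beta: np.ndarray, phi: float, X: np.ndarray, y: np.ndarray) -> float:
    """Fast path: total NB2 log-likelihood for a design array and count vector."""
    eta = X @ beta
    # guard against overflow in exp for extreme proposals
    if np.any(eta > 500):
        return -np.inf
    mu = np.exp(eta)
    t = phi + mu
    ll = (
        gammaln(y + phi).sum()
        - len(y) * gammaln(phi)
        - gammaln(y + 1.0).sum()
        + phi * (np.log(phi) * len(y) - np.log(t).sum())
        + (y * (eta - np.log(t))).sum()
    )
    return float(ll)


def _loglik_grad_raw(beta: np.ndarray, phi: float, X: np.ndarray, y: np.ndarray):
    """Analytic gradient of the total log-likelihood w.r.t. (beta, log phi)."""
    eta = X @ beta
    mu = np.exp(np.clip(eta, None, 500))
    t = phi + mu
    r = y - (y + phi) * mu / t  # d loglik / d eta
    g_beta = X.T @ r
    dphi = digamma(y + phi) - digamma(phi) + np.log(phi) + 1.0 - np.log(t) - (y + phi) / t
    g_logphi = phi * dphi.sum()
    return g_beta, float(g_logphi)


def log_likelihood(params: ParameterVector, design: DesignMatrix) -> float:
    """Total NB2 log-likelihood of a design under a parameter vector."""
    X = design.values
    if X.shape[1] != params.beta.shape[0]:
        raise ValueError(
            f"dimension mismatch: design has {X.shape[1]} columns, beta has {params.beta.shape[0]}"
        )
    return _loglik_raw(params.beta, params.phi, X, design.outcome.astype(float))


def log_posterior(params: ParameterVector, design: DesignMatrix,
                  prior: PriorSpec | None = None) -> float:
    """Flat-prior log posterior: the log-likelihood on the prior support, -inf off it."""
    prior = prior or PriorSpec()
    if not prior.in_support(params):
        return -np.inf
    return log_likelihood(params, design)


def dispersion_from_moments(mean: float, sd: float) -> float:
    """Invert the NB2 moment relation: ``phi = mean**2 / (sd**2 - mean)``.

    Calibration helper: given a published outcome mean and SD, return the
    dispersion of the NB2 distribution with those moments.

    Raises
    ------
    ValueError
        If ``sd**2 <= mean`` (the data are not over-dispersed relative to
        Poisson, so no NB2 dispersion exists).
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    excess = sd**2 - mean
    if excess <= 0:
        raise ValueError(f"not over-dispersed: sd^2 = {sd**2:g} <= mean = {mean:g}")
    return mean**2 / excess
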