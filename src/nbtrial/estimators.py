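"""Scikit-learn-style estimators for NB2 count regression.

Two estimators share the same log-link mean-dispersion negative binomial
likelihood: :class:`NegativeBinomialRegressor` maximizes it (L-BFGS-B with
analytic gradients, dispersion on the log scale) and
:class:`BayesianNegativeBinomialRegressor` samples the flat-prior posterior
with the adaptive-Metropolis engine.  Both follow the sklearn estimator
contract (``get_params``/``set_params``, ``fit``/``predict``, trailing-
underscore fitted attributes) and compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .mcmc import SamplerSettings, diagnostics, sample_posterior
from .model import ParameterVector, PriorSpec, _loglik_grad_raw, _loglik_raw


def _validate_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or (y != np.round(y)).any():
        raise ValueError("y must contain non-negative integer counts")
    return y


def _add_intercept(X: np.ndarray, fit_intercept: bool) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X]) if fit_intercept else X


class NegativeBinomialRegressor(RegressorMixin, BaseEstimator):
    """Maximum-likelihood NB2 regression with a log link.

    Model: ``y_i ~ NB2(mu_i, phi)`` with ``log mu_i = x_i' beta`` and
    variance ``mu_i + mu_i**2 / phi``.  The joint likelihood in
    ``(beta, log phi)`` is maximized with L-BFGS-B using analytic gradients;
    the parameter covariance is the inverse observed information at the
    optimum.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend an intercept column.  Set False when the design already
        carries one (e.g. a :class:`~nbtrial.data.DesignMatrix`).
    tol : float, default 1e-10
        Optimizer tolerance (on the scaled gradient).
    max_iter : int, default 500

    Attributes
    ----------
    coef_ : ndarray
        Coefficients of the features in X (excluding any fitted intercept).
    intercept_ : float
        0.0 when ``fit_intercept=False``.
    dispersion_ : float
        Estimated phi.
    cov_params_ : ndarray
        Observed-information covariance of ``(beta_full, log phi)`` where
        ``beta_full`` includes the intercept if fitted.
    loglik_ : float
        Log-likelihood at the optimum.
    converged_ : bool
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-10, max_iter: int = 500):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        y = _validate_counts(y)
        Xd = _add_intercept(X, self.fit_intercept)
        n, k = Xd.shape
        if n <= k:
            raise ValueError(f"need more rows ({n}) than parameters ({k})")
        if np.linalg.matrix_rank(Xd) < k:
            raise np.linalg.LinAlgError(
                "design matrix is rank deficient (e.g. a constant GROUP column)"
            )

        def negloglik(theta):
            return -_loglik_raw(theta[:k], float(np.exp(theta[k])), Xd, y)

        def grad(theta):
            g_beta, g_logphi = _loglik_grad_raw(theta[:k], float(np.exp(theta[k])), Xd, y)
            return -np.concatenate([g_beta, [g_logphi]])

        # start the intercept near log of the mean count if an intercept-like
        # (constant) column exists; otherwise from zero
        theta0 = np.zeros(k + 1)
        const_cols = np.flatnonzero(np.all(Xd == Xd[0], axis=0) & (Xd[0] != 0))
        if const_cols.size:
            theta0[const_cols[0]] = np.log(max(y.mean(), 0.5)) / Xd[0, const_cols[0]]

        res = optimize.minimize(
            negloglik, theta0, jac=grad, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": 1e-14, "gtol": self.tol * max(1.0, n)},
        )
        theta = res.x
        beta_full, log_phi = theta[:k], theta[k]

        hess = _numeric_hessian(grad, theta)
        try:
            cov = np.linalg.inv(0.5 * (hess + hess.T))
        except np.linalg.LinAlgError:
            cov = np.full((k + 1, k + 1), np.nan)

        gnorm = float(np.max(np.abs(grad(theta))))
        self.converged_ = bool(res.success or gnorm < 1e-3 * max(1.0, n))
        self.n_features_in_ = X.shape[1]
        if self.fit_intercept:
            self.intercept_ = float(beta_full[0])
            self.coef_ = beta_full[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta_full.copy()
        self.beta_full_ = beta_full.copy()
        self.dispersion_ = float(np.exp(log_phi))
        self.cov_params_ = cov
        self.loglik_ = float(-res.fun)
        self.n_iter_ = int(res.nit)
        return self

    def predict(self, X):
        """Expected counts ``mu = exp(intercept + X @ coef_)``."""
        check_is_fitted(self)
        X = check_array(X)
        return np.exp(self.intercept_ + X @ self.coef_)

    def parameter_vector(self) -> ParameterVector:
        check_is_fitted(self)
        return ParameterVector(beta=self.beta_full_, phi=self.dispersion_)


def _numeric_hessian(grad, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    d = theta.size
    H = np.empty((d, d))
    for j in range(d):
        step = eps * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        H[:, j] = (grad(tp) - grad(tm)) / (2 * step)
    return H


class BayesianNegativeBinomialRegressor(BaseEstimator):
    """Flat-prior Bayesian NB2 regression fitted by adaptive-Metropolis MCMC.

    The posterior is the NB2 likelihood under improper uniform priors on all
    coefficients and on the dispersion over the positive reals (optionally
    truncated).  ``fit`` runs multiple chains, stores the draws, and computes
    convergence diagnostics.

    Parameters
    ----------
    fit_intercept : bool, default True
    n_chains, n_iterations, n_warmup : int
        Chain layout (defaults 4 x 2,000 with 1,000 warmup).
    seed : int
        Master seed; fits are deterministic given it.
    init : {"mle", "default"}
        Start chains from the MLE (with its observed-information proposal
        covariance) or from the engine default (coefficients 0, phi 1),
        jittered per chain either way.
    beta_bounds, phi_bounds : pair of float, optional
        Finite truncation of the flat priors.

    Attributes
    ----------
    samples_ : PosteriorSamples
    diagnostics_ : DiagnosticsReport
    coef_, intercept_, dispersion_ : posterior means
    """

    def __init__(self, fit_intercept: bool = True, n_chains: int = 4,
                 n_iterations: int = 2000, n_warmup: int = 1000, seed: int = 0,
                 init: str = "mle", beta_bounds=None, phi_bounds=None):
        self.fit_intercept = fit_intercept
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.n_warmup = n_warmup
        self.seed = seed
        self.init = init
        self.beta_bounds = beta_bounds
        self.phi_bounds = phi_bounds

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        y = _validate_counts(y)
        Xd = _add_intercept(X, self.fit_intercept)
        k = Xd.shape[1]
        prior = PriorSpec(beta_bounds=self.beta_bounds, phi_bounds=self.phi_bounds)

        def target(pv: ParameterVector) -> float:
            if not prior.in_support(pv):
                return -np.inf
            return _loglik_raw(pv.beta, pv.phi, Xd, y)

        proposal_cov = None
        if self.init == "mle":
            mle = NegativeBinomialRegressor(fit_intercept=False).fit(Xd, y)
            init_pv = mle.parameter_vector()
            if np.all(np.isfinite(mle.cov_params_)):
                proposal_cov = mle.cov_params_
        elif self.init == "default":
            init_pv = ParameterVector(beta=np.zeros(k), phi=1.0)
        else:
            raise ValueError(f"unknown init {self.init!r}")

        settings = SamplerSettings(n_chains=self.n_chains, n_iterations=self.n_iterations,
                                   n_warmup=self.n_warmup, seed=self.seed)
        self.samples_ = sample_posterior(target, init_pv, settings, proposal_cov=proposal_cov)
        self.diagnostics_ = diagnostics(self.samples_)

        pooled = self.samples_.post_warmup().reshape(-1, k + 1)
        mean = pooled.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        if self.fit_intercept:
            self.intercept_ = float(mean[0])
            self.coef_ = mean[1:k].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = mean[:k].copy()
        self.dispersion_ = float(mean[k])
        return self

    def predict(self, X):
        """Posterior-mean expected counts."""
        check_is_fitted(self)
        X = check_array(X)
        return np.exp(self.intercept_ + X @ self.coef_)

    def coefficient_draws(self, index: int) -> np.ndarray:
        """Pooled post-warmup draws of one full-design coefficient."""
        check_is_fitted(self)
        pw = self.samples_.post_warmup()
        return pw.reshape(-1, pw.shape[-1])[:, index]
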