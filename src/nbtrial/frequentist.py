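"""Null-hypothesis analysis: NB2 MLE, IRR with 95% Wald CI, two-tailed P.

Thin functional layer over :class:`~nbtrial.estimators.NegativeBinomialRegressor`
operating on :class:`~nbtrial.data.DesignMatrix` objects.  The incidence rate
ratio (IRR) is ``exp(theta_hat_GROUP)``; its Wald interval is
``exp(theta_hat +- 1.96 * SE)`` and the P value comes from the two-tailed
normal test of ``theta_hat / SE``.  The raw P value is reported; no
significance verdict is attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import DesignMatrix
from .estimators import NegativeBinomialRegressor
from .model import ParameterVector

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class MLEFit:
    """A converged (or flagged) maximum-likelihood fit tied to its design layout."""

    params: ParameterVector
    cov_params: np.ndarray  # covariance of (beta, log phi)
    converged: bool
    loglik: float
    column_map: list[tuple[str, str]]
    arm_labels: tuple[str, str]

    def group_index(self) -> int:
        for j, (src, _) in enumerate(self.column_map):
            if src == "group":
                return j
        raise KeyError("fit has no GROUP coefficient")


@dataclass
class FrequentistResult:
    """IRR point estimate, 95% Wald CI and two-tailed P value."""

    irr: float
    ci95: tuple[float, float]
    p_value: float
    log_irr: float
    se_log_irr: float

    def to_dict(self) -> dict:
        return {
            "irr": self.irr,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p_value": self.p_value,
            "log_irr": self.log_irr,
            "se_log_irr": self.se_log_irr,
        }


def fit_mle(design: DesignMatrix) -> MLEFit:
    """Maximize the NB2 likelihood on a full-rank design.

    Raises
    ------
    numpy.linalg.LinAlgError
        If the design is rank deficient.
    """
    est = NegativeBinomialRegressor(fit_intercept=False).fit(design.values, design.outcome)
    return MLEFit(
        params=est.parameter_vector(),
        cov_params=est.cov_params_,
        converged=est.converged_,
        loglik=est.loglik_,
        column_map=list(design.column_map),
        arm_labels=design.arm_labels,
    )


def wald_irr(fit: MLEFit) -> FrequentistResult:
    """IRR, 95% Wald CI and two-tailed P for the GROUP coefficient.

    Raises
    ------
    RuntimeError
        If the fit did not converge.
    """
    if not fit.converged:
        raise RuntimeError("refusing inference on a non-converged fit")
    j = fit.group_index()
    log_irr = float(fit.params.beta[j])
    se = float(np.sqrt(fit.cov_params[j, j]))
    z = log_irr / se
    p = float(2 * stats.norm.sf(abs(z)))
    return FrequentistResult(
        irr=float(np.exp(log_irr)),
        ci95=(float(np.exp(log_irr - Z_95 * se)), float(np.exp(log_irr + Z_95 * se))),
        p_value=max(p, np.finfo(float).tiny),
        log_irr=log_irr,
        se_log_irr=se,
    )


def model_based_moments(fit: MLEFit, design: DesignMatrix) -> dict[str, tuple[float, float]]:
    """Per-arm model-based outcome mean and SD.

    Mean is the average fitted ``mu_i`` over the arm's rows; SD is the square
    root of the average conditional variance ``mu_i + mu_i**2/phi_hat``
    (i.e. moments of the fitted model averaged over the arm's realized
    covariates).

    Raises
    ------
    RuntimeError / ValueError
        On a non-converged fit or an empty arm.
    """
    if not fit.converged:
        raise RuntimeError("refusing inference on a non-converged fit")
    mu = np.exp(design.values @ fit.params.beta)
    phi = fit.params.phi
    out: dict[str, tuple[float, float]] = {}
    for arm in design.arm_labels:
        mask = design.arm_mask(arm)
        if not mask.any():
            raise ValueError(f"arm {arm!r} has no rows")
        m = mu[mask]
        out[arm] = (float(m.mean()), float(np.sqrt((m + m**2 / phi).mean())))
    return out
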