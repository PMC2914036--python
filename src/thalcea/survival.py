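"""Weibull proportional-hazards survival machinery.

The transplant cohort's time-to-death and time-to-graft-failure are
modelled with Weibull regressions in the proportional-hazards
parameterization

    S(t) = exp{-H(t)},     H(t) = lambda * t**gamma,

with ``t`` in days.  Covariates enter the scale on the log scale,
``lambda = exp(constant + sum(coef * x))``, and the shape is stored as
its log (the "ancillary" parameter), ``gamma = exp(ancillary)``, the
convention of standard survival software.  The death model carries the
age-at-start covariate (years); the failure model carries the donor-type
covariate (related = 0, unrelated = 1).

Per-cycle transition probabilities for a Markov model with cycle length
``u`` follow from the cumulative hazard increment:

    tp(u) = 1 - exp{H(t - u) - H(t)}.

With ``gamma < 1`` the hazard is front-loaded: tp decreases as time
since transplant grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools import numdiff

from .params import ParameterSet

__all__ = [
    "WeibullCoefficients",
    "scale_lambda",
    "cumulative_hazard",
    "survival_function",
    "cycle_transition_probability",
    "fit_weibull_mle",
    "FittedWeibull",
    "DEATH_MODEL",
    "FAILURE_MODEL",
]

#: registry parameter names backing each fitted model
DEATH_MODEL = {
    "constant": "death_constant",
    "covariates": {"age_at_start_years": "death_age_coefficient"},
    "ancillary": "death_ancillary",
}
FAILURE_MODEL = {
    "constant": "failure_constant",
    "covariates": {"donor_type": "failure_donor_type_coefficient"},
    "ancillary": "failure_ancillary",
}


@dataclass(frozen=True)
class WeibullCoefficients:
    """Log-scale Weibull PH regression parameters with named covariates."""

    constant: float
    covariates: Mapping[str, float] = field(default_factory=dict)
    ancillary: float = 0.0

    @property
    def shape(self) -> float:
        """Weibull shape gamma = exp(ancillary) > 0."""
        return float(np.exp(self.ancillary))

    @classmethod
    def from_parameter_set(
        cls, params: ParameterSet, model: str
    ) -> "WeibullCoefficients":
        """Build coefficients from a realized parameter set.

        ``model`` is ``"death"`` (age covariate) or ``"failure"``
        (donor-type covariate).
        """
        spec = {"death": DEATH_MODEL, "failure": FAILURE_MODEL}[model]
        return cls(
            constant=params[spec["constant"]],
            covariates={k: params[v] for k, v in spec["covariates"].items()},
            ancillary=params[spec["ancillary"]],
        )


def scale_lambda(
    coeffs: WeibullCoefficients, covariate_values: Mapping[str, float]
) -> float:
    """Scale parameter lambda = exp(constant + sum(coef_i * x_i))."""
    lp = coeffs.constant
    for name, coef in coeffs.covariates.items():
        if name not in covariate_values:
            raise KeyError(f"missing covariate {name!r}")
        lp += coef * covariate_values[name]
    return float(np.exp(lp))


def cumulative_hazard(lam: float, gamma: float, t) -> float | np.ndarray:
    """Cumulative hazard H(t) = lambda * t**gamma, t in days."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = lam * t**gamma
    return float(out) if out.ndim == 0 else out


def survival_function(lam: float, gamma: float, t) -> float | np.ndarray:
    """S(t) = exp(-H(t))."""
    return np.exp(-cumulative_hazard(lam, gamma, t))


def cycle_transition_probability(lam, gamma, t: float, u: float = 365.0):
    """Per-cycle event probability tp(u) = 1 - exp{H(t-u) - H(t)}.

    ``t`` is time (days) at the end of the cycle, ``u`` the cycle length;
    the first cycle (t == u) reduces to 1 - S(u).  ``lam`` and ``gamma``
    may be arrays (broadcast), supporting vectorized PSA evaluation.
    """
    if u <= 0:
        raise ValueError("cycle length u must be > 0")
    if t < u:
        raise ValueError(f"t ({t}) must be >= cycle length u ({u})")
    lam = np.asarray(lam, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    out = 1.0 - np.exp(lam * (t - u) ** gamma - lam * t**gamma)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FittedWeibull:
    """MLE result: point estimates, asymptotic SEs, covariance, fit info."""

    coefficients: WeibullCoefficients
    standard_errors: Mapping[str, float]
    covariance: np.ndarray
    log_likelihood: float
    n_events: int
    n_observations: int

    def confidence_interval(self, name: str, z: float = 1.959964) -> tuple[float, float]:
        est = (
            self.coefficients.constant
            if name == "constant"
            else self.coefficients.ancillary
            if name == "ancillary"
            else self.coefficients.covariates[name]
        )
        se = self.standard_errors[name]
        return est - z * se, est + z * se


def _neg_loglik(theta: np.ndarray, t: np.ndarray, d: np.ndarray, x: np.ndarray | None):
    const, anc = theta[0], theta[-1]
    lp = const + (theta[1] * x if x is not None else 0.0)
    gamma = np.exp(anc)
    log_h = lp + anc + (gamma - 1.0) * np.log(t)
    H = np.exp(lp) * t**gamma
    return -(np.sum(d * log_h) - np.sum(H))


def fit_weibull_mle(
    records: pd.DataFrame | Sequence,
    event_of_interest: str,
    covariate: str | None = None,
) -> FittedWeibull:
    """Right-censored Weibull PH maximum-likelihood fit.

    Parameters
    ----------
    records
        Patient-level data with columns ``time_days`` (> 0), ``event``
        (one of ``death``, ``failure``, ``censored``) and, if
        ``covariate`` is given, that column.  ``donor_type`` may be coded
        as strings (``related``/``unrelated``) or 0/1.
    event_of_interest
        Which event counts as a failure for this fit; every other record
        is treated as right-censored at its observed time (competing
        events are censored, matching the fitting of two separate
        cause-specific models).
    covariate
        Optional single covariate entering the log-scale linearly.

    Returns point estimates for (constant, covariate coefficient,
    ancillary = log shape) and their asymptotic standard errors from the
    inverse observed information.
    """
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    t = frame["time_days"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("all event times must be > 0")
    d = (frame["event"] == event_of_interest).to_numpy(dtype=float)
    n_events = int(d.sum())
    if n_events < 2:
        raise ValueError(
            f"need >= 2 {event_of_interest!r} events to fit, got {n_events}"
        )
    x = None
    if covariate is not None:
        col = frame[covariate]
        if col.dtype == object:
            x = (col == "unrelated").to_numpy(dtype=float)
        else:
            x = col.to_numpy(dtype=float)

    # start: log crude event rate per day, coefficients 0, ancillary 0
    theta0 = np.zeros(2 if x is None else 3)
    theta0[0] = np.log(n_events / t.sum())
    res = optimize.minimize(
        _neg_loglik, theta0, args=(t, d, x), method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not res.success and res.status != 2:  # 2: precision loss at optimum
        raise RuntimeError(f"Weibull MLE did not converge: {res.message}")
    hess = numdiff.approx_hess(res.x, _neg_loglik, args=(t, d, x))
    cov = np.linalg.inv(hess)
    ses = np.sqrt(np.diag(cov))
    if x is None:
        coeffs = WeibullCoefficients(constant=res.x[0], ancillary=res.x[1])
        se_map = {"constant": ses[0], "ancillary": ses[1]}
    else:
        coeffs = WeibullCoefficients(
            constant=res.x[0], covariates={covariate: res.x[1]}, ancillary=res.x[2]
        )
        se_map = {"constant": ses[0], covariate: ses[1], "ancillary": ses[2]}
    return FittedWeibull(
        coefficients=coeffs,
        standard_errors=se_map,
        covariance=cov,
        log_likelihood=-res.fun,
        n_events=n_events,
        n_observations=len(t),
    )
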