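"""Hazard and piecewise-exponential survival arithmetic.

All computation lives in the log domain: the per-interval contribution to
the survival log-likelihood is

    delta_bar_j * (gamma' omega + alpha' H x_j)
        - tau_j * exp(gamma' omega + alpha' H x_j)

and under the step-constant-state assumption the survival function over a
path is the product of interval-wise exponentials,
S(T) = exp(-sum_j tau_j * h_j).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "log_hazard",
    "interval_survival_logpdf",
    "piecewise_survival",
    "gaussian_exp_moment",
]

#: bound on |log hazard| before clipping; transiently extreme coefficients
#: proposed by inner Newton iterations must not overflow exp()
LOG_HAZARD_BOUND = 50.0


def _clip_log_hazard(eta):
    eta = np.asarray(eta, dtype=float)
    if np.any(np.abs(eta) > LOG_HAZARD_BOUND):
        warnings.warn(
            f"log-hazard clipped at +/-{LOG_HAZARD_BOUND}", RuntimeWarning, stacklevel=3
        )
        eta = np.clip(eta, -LOG_HAZARD_BOUND, LOG_HAZARD_BOUND)
    return eta


def log_hazard(x, omega, params) -> float:
    """Log hazard ``gamma' omega + alpha' H x`` for one state vector."""
    x = np.asarray(x, dtype=float).ravel()
    omega = np.asarray(omega, dtype=float).ravel()
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(omega))):
        raise ValueError("non-finite inputs to log_hazard")
    eta = params.gamma @ omega + params.alpha @ (params.structure.H @ x)
    return float(eta)


def interval_survival_logpdf(x_j, omega, tau_j, delta_bar_j, params) -> float:
    """Log-probability contribution of one grid interval's survival outcome."""
    if tau_j < 0:
        raise ValueError("negative exposure tau_j")
    eta = log_hazard(x_j, omega, params)
    return float(delta_bar_j * eta - tau_j * np.exp(_clip_log_hazard(eta)))


def piecewise_survival(x_path, omega, tau, params) -> float:
    """Piecewise-exponential survival probability along a state path.

    ``S = exp(-sum_j tau_j exp(gamma' omega + alpha' H x_j))`` with the
    hazard held constant within each interval.
    """
    x_path = np.atleast_2d(np.asarray(x_path, dtype=float))
    tau = np.asarray(tau, dtype=float).ravel()
    if x_path.shape[0] != tau.size:
        raise ValueError("x_path and tau must have the same length")
    if np.any(tau < 0):
        raise ValueError("negative exposure in tau")
    omega = np.asarray(omega, dtype=float).ravel()
    eta = params.gamma @ omega + x_path @ params.structure.H.T @ params.alpha
    cum_haz = float(np.sum(tau * np.exp(_clip_log_hazard(eta))))
    return float(np.exp(-cum_haz))


def gaussian_exp_moment(mu, Sigma, a) -> float:
    """E[exp(a'x)] for x ~ N(mu, Sigma): the Gaussian moment generating function.

    Exact for Gaussian inputs: ``exp(a'mu + a'Sigma a / 2)``.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    a = np.asarray(a, dtype=float).ravel()
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    if not np.allclose(Sigma, Sigma.T, atol=1e-8):
        raise ValueError("Sigma must be symmetric")
    return float(np.exp(a @ mu + 0.5 * a @ Sigma @ a))
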