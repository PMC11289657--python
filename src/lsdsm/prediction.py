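"""Individualized dynamic survival prediction.

From a landmark time ``t_s`` (using all of a patient's data up to it,
and the fact that the patient is alive at it), the conditional survival
curve over a horizon is built by repeating three steps on the carried
Gaussian state belief:

1. one-step-ahead prediction of the hidden states;
2. a Laplace re-approximation of the state conditioned on surviving the
   step (the filter's survival correction with no measurement and no
   event); and
3. the one-step conditional survival increment
   ``P(survive step) = E[exp(-tau h(x))]`` under the predicted belief.

The hazard depends on the state only through the scalar ``s = alpha'H x``,
so both steps reduce to one-dimensional integrals.  The default
(``method="moment_match"``) evaluates them exactly by Gauss-Hermite
quadrature: the increment is ``E[exp(-tau e^{g+s})]`` and the survivors'
belief is the Gaussian with the exact first two moments of the tilted
distribution, updated along the ``Sigma H'alpha`` direction.  Against
exact density propagation this keeps the curve error well below Monte-
Carlo resolution at 1e5 draws.

Alternatives: ``method="laplace"`` re-approximates the survivors around
the posterior mode with curvature from the Hessian and takes the
increment from the same Laplace integral (the mode/Hessian construction
used inside the filter); ``method="quadrature"`` combines the exact
increment with the mode-based correction; ``method="moment"`` is the
crude plug-in ``exp(-tau E[h])`` via the Gaussian exponential moment.

The recursion starts from the survival-corrected filtered belief at the
patient's last landmark step, so the initial belief already conditions
on survival to the landmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .canonical import ModelParameters
from .filtering import (
    GaussianBelief,
    NewtonConfig,
    filter_patient,
    survival_measurement_update,
    time_update,
)
from .gridding import GriddedPatient
from .hazards import gaussian_exp_moment

__all__ = ["SurvivalCurve", "predict_survival"]


@dataclass
class SurvivalCurve:
    """Predicted conditional survival S(t | alive at landmark, data to landmark)."""

    patient_id: object
    landmark: float
    horizon_times: np.ndarray   # starts at the landmark
    survival: np.ndarray        # survival[0] == 1.0

    def at(self, t: float) -> float:
        """Survival at the grid time closest to ``t``."""
        return float(self.survival[np.argmin(np.abs(self.horizon_times - t))])


def _moment_match_step(belief: GaussianBelief, g: float, a, tau: float):
    """Exact one-step survival increment and moment-matched survivors'
    belief, via Gauss-Hermite quadrature on the scalar s = a'x."""
    Sa = belief.Sigma @ a
    m_s = float(a @ belief.mu)
    v_s = float(a @ Sa)
    if v_s < 1e-14:
        inc = float(np.exp(-tau * np.exp(np.clip(g + m_s, -700, 700))))
        return inc, belief
    nodes, wts = np.polynomial.hermite_e.hermegauss(60)
    wts = wts / np.sqrt(2 * np.pi)
    sv = m_s + np.sqrt(v_s) * nodes
    f = np.exp(-tau * np.exp(np.clip(g + sv, -700, 700)))
    Z = float(np.sum(wts * f))
    m_t = float(np.sum(wts * f * sv) / Z)
    v_t = float(np.sum(wts * f * (sv - m_t) ** 2) / Z)
    mu_new = belief.mu + Sa * (m_t - m_s) / v_s
    Sigma_new = belief.Sigma + np.outer(Sa, Sa) * (v_t - v_s) / v_s**2
    return Z, GaussianBelief(mu_new, Sigma_new)


def _one_step_log_survival(belief: GaussianBelief, g: float, a, tau: float,
                           method: str, corrected: GaussianBelief | None = None) -> float:
    """log P(survive an interval of exposure tau) under a Gaussian state belief."""
    if method == "laplace":
        # Laplace approximation of the integral, sharing the mode and
        # curvature with the survived-the-step correction
        d = corrected.mu - belief.mu
        sol = np.linalg.solve(belief.Sigma, d)
        h_mode = tau * np.exp(np.clip(g + a @ corrected.mu, -700, 700))
        _, logdet_prior = np.linalg.slogdet(belief.Sigma)
        _, logdet_post = np.linalg.slogdet(corrected.Sigma)
        return float(-h_mode - 0.5 * d @ sol + 0.5 * (logdet_post - logdet_prior))
    if method == "moment":
        e_haz = np.exp(g) * gaussian_exp_moment(belief.mu, belief.Sigma, a)
        return -tau * e_haz
    if method == "quadrature":
        # hazard depends on x only through s = a'x ~ N(a'mu, a'Sigma a):
        # integrate exp(-tau e^{g+s}) exactly by Gauss-Hermite
        mu_s = float(a @ belief.mu)
        var_s = float(a @ belief.Sigma @ a)
        nodes, wts = np.polynomial.hermite_e.hermegauss(40)
        s_vals = mu_s + np.sqrt(max(var_s, 0.0)) * nodes
        vals = np.exp(-tau * np.exp(np.clip(g + s_vals, -700, 700)))
        return float(np.log(np.sum(wts * vals) / np.sqrt(2 * np.pi)))
    raise ValueError(f"unknown increment method {method!r}")


def predict_survival(
    patient: GriddedPatient,
    params: ModelParameters,
    t_h: float,
    landmark: float | None = None,
    nr_config: NewtonConfig | None = None,
    method: str = "moment_match",
) -> SurvivalCurve:
    """Conditional survival curve from ``landmark`` out to ``landmark + t_h``.

    ``landmark`` defaults to the end of the patient's record rounded to
    the grid; otherwise it must be a grid multiple within the record
    (off-grid landmarks are floored with a warning).  The patient record
    is administratively truncated (treated as alive and censored) at the
    landmark before filtering.
    """
    if t_h < 0:
        raise ValueError("horizon t_h must be non-negative")
    dt = patient.dt
    if landmark is None:
        n_steps = patient.m
    else:
        ratio = landmark / dt
        if abs(ratio - round(ratio)) > 1e-9:
            warnings.warn(
                f"landmark {landmark} is not a grid multiple; flooring to the grid",
                RuntimeWarning,
            )
        n_steps = int(np.floor(ratio + 1e-9))
        if n_steps < 1 or n_steps * dt > patient.m * dt + 1e-9:
            raise ValueError(
                f"landmark {landmark} outside the patient's observed record"
            )
        n_steps = min(n_steps, patient.m)
    t_s = n_steps * dt

    truncated = patient.truncated(n_steps)
    fr = filter_patient(truncated, params, nr_config)
    belief = GaussianBelief(fr.filt_mu[-1], fr.filt_Sigma[-1])

    s = params.structure
    g = float(params.gamma @ patient.omega)
    a = s.H.T @ params.alpha

    n_full = int(np.floor(t_h / dt + 1e-9))
    tau_last = t_h - n_full * dt
    taus = [dt] * n_full + ([tau_last] if tau_last > 1e-12 else [])

    times = [t_s]
    surv = [1.0]
    log_s = 0.0
    mask = np.zeros(s.m_y, dtype=bool)
    y_dummy = np.full(s.m_y, np.nan)
    for tau in taus:
        belief = time_update(belief, params)
        if method == "moment_match":
            inc, corrected = _moment_match_step(belief, g, a, tau)
            log_s += float(np.log(max(inc, 1e-300)))
        else:
            # mode/Hessian re-approximation of the survivors, shared with
            # the Laplace increment
            corrected = survival_measurement_update(
                belief, y_dummy, mask, patient.omega, tau, 0.0, params, nr_config
            )
            log_s += _one_step_log_survival(belief, g, a, tau, method, corrected)
        times.append(times[-1] + tau)
        surv.append(float(np.exp(log_s)))
        belief = corrected
    return SurvivalCurve(
        patient_id=patient.patient_id,
        landmark=t_s,
        horizon_times=np.asarray(times),
        survival=np.asarray(surv),
    )
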