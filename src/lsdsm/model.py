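"""Model/Results surface for the joint state-space survival model.

Follows the statsmodels idiom: :class:`LSDSM` is constructed from data
(a gridded cohort, or long-format tables via :meth:`LSDSM.from_dataframes`),
``fit()`` runs the EM algorithm and returns an :class:`LSDSMResults`
carrying the estimates, convergence diagnostics, ``summary()``, smoothing
and dynamic survival prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import em
from .canonical import ModelParameters, build_canonical_structure
from .filtering import NewtonConfig, SmoothedMoments
from .gridding import GriddedPatient, grid_cohort
from .hazards import gaussian_exp_moment
from .prediction import SurvivalCurve, predict_survival

__all__ = ["LSDSM", "LSDSMResults"]


class LSDSM:
    """Joint model of longitudinal biomarkers and survival.

    A canonical AR(M) linear-Gaussian state space model tracks the true
    biomarker trajectories; its hidden states drive a proportional-
    hazards model, h_i(t) = exp(gamma' omega_i + alpha' H x_i(t)).

    Parameters
    ----------
    patients : list of GriddedPatient
        The discretized cohort.
    M : int
        Autoregressive order of the latent process.
    H : ndarray, optional
        Hazard-association matrix; defaults to current-value
        association ``[I 0]``.
    """

    def __init__(self, patients: list[GriddedPatient], M: int = 2,
                 H: np.ndarray | None = None):
        if not patients:
            raise ValueError("empty cohort")
        m_y = patients[0].y.shape[1]
        m_omega = patients[0].omega.size
        for p in patients:
            if p.y.shape[1] != m_y or p.omega.size != m_omega:
                raise ValueError(f"inconsistent dimensions for patient {p.patient_id!r}")
        self.patients = patients
        self.structure = build_canonical_structure(m_y=m_y, M=M, H=H, m_omega=m_omega)

    @classmethod
    def from_dataframes(
        cls,
        longitudinal: pd.DataFrame,
        baseline: pd.DataFrame,
        survival: pd.DataFrame,
        dt: float,
        M: int = 2,
        H: np.ndarray | None = None,
        add_intercept: bool = True,
        aggregate: str = "mean",
    ) -> "LSDSM":
        """Build the model from long-format tables (see :func:`grid_cohort`)."""
        patients = grid_cohort(
            longitudinal, baseline, survival, dt=dt,
            aggregate=aggregate, add_intercept=add_intercept,
        )
        return cls(patients, M=M, H=H)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def start_params(self) -> ModelParameters:
        """Default data-driven starting values for EM."""
        return em.initialize(self.patients, self.structure)

    def fit(
        self,
        config: em.FitConfig | None = None,
        start_params: ModelParameters | None = None,
        **config_kwargs,
    ) -> "LSDSMResults":
        """Estimate theta by EM; returns an :class:`LSDSMResults`."""
        if config is None:
            config = em.FitConfig(**config_kwargs)
        elif config_kwargs:
            raise TypeError("pass either config or keyword settings, not both")
        res = em.fit(self.patients, self.structure, config, theta0=start_params)
        return LSDSMResults(model=self, _fit=res, config=config)


@dataclass
class LSDSMResults:
    """Estimation output: parameter estimates, diagnostics and predictions."""

    model: LSDSM
    _fit: em.FitResult
    config: em.FitConfig

    @property
    def params(self) -> ModelParameters:
        return self._fit.theta_hat

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def n_iter(self) -> int:
        return self._fit.n_iter

    @property
    def q_trace(self) -> list[float]:
        """Expected complete-data log-likelihood after each EM iteration."""
        return self._fit.q_trace

    def smoothed(self, nr_config: NewtonConfig | None = None) -> list[SmoothedMoments]:
        """Smoothed state posteriors for every patient under the estimates."""
        stats = em.e_step(
            self.model.patients, self.params,
            nr_config or self.config.nr_config, keep_per_patient=True,
        )
        return stats.per_patient

    def smoothed_survival_curves(
        self, smoothed: list[SmoothedMoments] | None = None
    ) -> list[np.ndarray]:
        """In-sample survival curves from the smoothed state posteriors.

        For each patient, S(t_j) = exp(-sum_{l<=j} tau_l E[h_l]) with the
        expected hazard from the Gaussian exponential moment of the
        smoothed posterior.
        """
        theta = self.params
        s = theta.structure
        a = s.H.T @ theta.alpha
        smoothed = smoothed or self.smoothed()
        curves = []
        for p, mom in zip(self.model.patients, smoothed):
            g = float(theta.gamma @ p.omega)
            e_h = np.array(
                [
                    np.exp(g) * gaussian_exp_moment(mom.mu_hat[j], mom.Sigma_hat[j], a)
                    for j in range(p.m)
                ]
            )
            curves.append(np.exp(-np.cumsum(p.tau * e_h)))
        return curves

    def predict_survival(
        self,
        patient: GriddedPatient | object,
        t_h: float,
        landmark: float | None = None,
        method: str = "moment",
    ) -> SurvivalCurve:
        """Dynamic survival prediction for one patient (by object or id)."""
        if not isinstance(patient, GriddedPatient):
            matches = [p for p in self.model.patients if p.patient_id == patient]
            if not matches:
                raise KeyError(f"unknown patient {patient!r}")
            patient = matches[0]
        return predict_survival(
            patient, self.params, t_h, landmark=landmark,
            nr_config=self.config.nr_config, method=method,
        )

    def summary(self) -> str:
        """Plain-text estimation summary."""
        th = self.params
        s = th.structure
        lines = [
            "Joint longitudinal-survival state space model (LSDSM)",
            "=" * 56,
            f"patients: {self.model.n_patients}    biomarkers: {s.m_y}    "
            f"AR order: {s.M}",
            f"EM iterations: {self.n_iter}    converged: {self.converged}",
            "",
            "Transition block A_bar:",
            np.array2string(th.A_bar, precision=4),
            f"Disturbance covariance W_breve: {np.array2string(th.W_breve, precision=5)}",
            f"Measurement covariance V:       {np.array2string(th.V, precision=5)}",
            f"Initial state mean x1_bar:      {np.array2string(th.x1_bar, precision=4)}",
            "Initial state covariance W1_bar:",
            np.array2string(th.W1_bar, precision=4),
            "",
            "Hazard coefficients (log hazard ratios):",
            f"  gamma (baseline covariates): {np.array2string(th.gamma, precision=4)}",
            f"  alpha (state association):   {np.array2string(th.alpha, precision=4)}",
            "  hazard ratios exp(gamma):    "
            + np.array2string(np.exp(th.gamma), precision=4),
            "  hazard ratios exp(alpha):    "
            + np.array2string(np.exp(th.alpha), precision=4),
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize the estimates (with fit provenance) to JSON."""
        self.params.to_json(
            path,
            tol=self.config.tol,
            max_iter=self.config.max_iter,
            n_iter=self.n_iter,
            converged=self.converged,
        )
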