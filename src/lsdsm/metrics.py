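"""Landmark/horizon predictive performance metrics.

Discrimination is measured by the cumulative/dynamic AUC over the window
``(t_s, t_s + t_h]`` and calibration-plus-discrimination by the
time-dependent Brier score at ``t_s + t_h``, both restricted to patients
still at risk at the landmark ``t_s`` and weighted by inverse
probability of censoring (Kaplan-Meier estimate of the censoring
distribution, conditioned on being uncensored at the landmark).  Without
censoring both reduce to their plain empirical counterparts.  Tracking
accuracy of latent trajectories and of survival curves is summarized by
pooled RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "LandmarkEvaluation",
    "dynamic_auc",
    "brier_score",
    "rmse_trajectory",
    "rmse_survival",
    "evaluate_landmarks",
]


@dataclass
class LandmarkEvaluation:
    """One (landmark, horizon) cell of an evaluation report."""

    landmark: float
    horizon: float
    auc: float
    brier: float
    n_at_risk: int


def _censoring_weights(T, delta, t_s):
    """KM estimate G of the censoring survival among the at-risk set,
    conditioned on being uncensored at t_s; returns a callable G_cond(t)."""
    km = KaplanMeierFitter()
    km.fit(T, event_observed=1 - np.asarray(delta))
    G = lambda t: np.clip(
        km.survival_function_at_times(np.atleast_1d(t)).to_numpy(), 1e-12, None
    )
    G_s = G(t_s)[0]
    return lambda t: G(t) / G_s


def _at_risk(T, delta, t_s, *arrays):
    T = np.asarray(T, dtype=float)
    delta = np.asarray(delta)
    keep = T > t_s
    out = [T[keep], delta[keep]]
    for a in arrays:
        out.append(np.asarray(a)[keep])
    return out


def dynamic_auc(risk_scores, T, delta, t_s, t_h, weighting="ipcw") -> float:
    """Cumulative/dynamic AUC over ``(t_s, t_s + t_h]``.

    Cases are at-risk patients with an observed event in the window;
    controls are patients surviving past the horizon.  Ties in the risk
    score count one half.  ``weighting="ipcw"`` applies Kaplan-Meier
    inverse-censoring weights; ``"none"`` gives the unweighted AUC.
    """
    T_r, d_r, s_r = _at_risk(T, delta, t_s, risk_scores)
    horizon = t_s + t_h
    case = (T_r <= horizon) & (d_r == 1)
    control = T_r > horizon
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(
            f"dynamic AUC undefined: {case.sum()} cases and "
            f"{control.sum()} controls in ({t_s}, {horizon}]"
        )
    if weighting == "ipcw":
        G = _censoring_weights(T_r, d_r, t_s)
        eps = 1e-9 * (1.0 + np.abs(T_r[case]))
        w_case = 1.0 / G(T_r[case] - eps)
        w_ctrl = np.full(control.sum(), 1.0 / G(horizon)[0])
    elif weighting == "none":
        w_case = np.ones(case.sum())
        w_ctrl = np.ones(control.sum())
    else:
        raise ValueError("weighting must be 'ipcw' or 'none'")
    sc, st = s_r[case], s_r[control]
    diff = sc[:, None] - st[None, :]
    conc = (diff > 0) + 0.5 * (diff == 0)
    wmat = w_case[:, None] * w_ctrl[None, :]
    return float(np.sum(wmat * conc) / np.sum(wmat))


def brier_score(predicted_survival, T, delta, t_s, t_h, weighting="ipcw") -> float:
    """IPCW time-dependent Brier score at ``t_s + t_h``.

    ``predicted_survival`` are conditional survival probabilities at the
    horizon given survival to the landmark, aligned with ``T``/``delta``.
    Patients censored inside the window get zero weight.
    """
    T_r, d_r, p_r = _at_risk(T, delta, t_s, predicted_survival)
    horizon = t_s + t_h
    event_in = (T_r <= horizon) & (d_r == 1)
    beyond = T_r > horizon
    if weighting == "ipcw":
        G = _censoring_weights(T_r, d_r, t_s)
        eps = 1e-9 * (1.0 + np.abs(T_r))
        w = np.zeros(T_r.size)
        w[event_in] = 1.0 / G(T_r - eps)[event_in]
        w[beyond] = 1.0 / G(horizon)[0]
    elif weighting == "none":
        w = (event_in | beyond).astype(float)
    else:
        raise ValueError("weighting must be 'ipcw' or 'none'")
    status = beyond.astype(float)        # 1 if still alive at the horizon
    return float(np.sum(w * (status - p_r) ** 2) / T_r.size)


def _pool(pairs):
    se = 0.0
    count = 0
    for est, true in pairs:
        est = np.asarray(est, dtype=float)
        true = np.asarray(true, dtype=float)
        if est.shape != true.shape:
            raise ValueError(f"shape mismatch {est.shape} vs {true.shape}")
        se += float(np.sum((est - true) ** 2))
        count += est.size
    return se, count


def rmse_trajectory(estimated_states, true_states, per_patient: bool = False) -> float:
    """RMSE of estimated vs true leading-state trajectories.

    Inputs are equal-length sequences of per-patient arrays on matching
    grids.  Pooled over all patient-time points by default; with
    ``per_patient=True`` the per-patient RMSEs are averaged instead.
    """
    if per_patient:
        vals = []
        for est, true in zip(estimated_states, true_states):
            se, cnt = _pool([(est, true)])
            vals.append(np.sqrt(se / cnt))
        return float(np.mean(vals))
    se, cnt = _pool(zip(estimated_states, true_states))
    return float(np.sqrt(se / cnt))


def rmse_survival(estimated_curves, true_curves, per_patient: bool = False) -> float:
    """RMSE of predicted vs true survival probabilities over patients' grids."""
    return rmse_trajectory(estimated_curves, true_curves, per_patient=per_patient)


def evaluate_landmarks(
    predictions: pd.DataFrame,
    survival: pd.DataFrame,
    landmarks,
    horizons,
    weighting: str = "ipcw",
) -> pd.DataFrame:
    """Build a (landmark, horizon) report from per-patient predicted curves.

    ``predictions`` has columns ``patient_id, landmark, horizon_time,
    survival_probability`` (as written by the prediction CLI);
    ``survival`` has ``patient_id, time, event``.  The risk score for the
    AUC is one minus the predicted conditional survival at the horizon.
    """
    surv = survival.set_index("patient_id")
    rows = []
    for t_s in np.atleast_1d(landmarks):
        pred_s = predictions[np.isclose(predictions["landmark"], t_s)]
        if pred_s.empty:
            raise ValueError(f"no predictions at landmark {t_s}")
        for t_h in np.atleast_1d(horizons):
            horizon = t_s + t_h
            pids, probs = [], []
            for pid, grp in pred_s.groupby("patient_id"):
                tgrid = grp["horizon_time"].to_numpy(dtype=float)
                k = np.argmin(np.abs(tgrid - horizon))
                pids.append(pid)
                probs.append(float(grp["survival_probability"].to_numpy()[k]))
            T = surv.loc[pids, "time"].to_numpy(dtype=float)
            delta = surv.loc[pids, "event"].to_numpy(dtype=int)
            probs = np.asarray(probs)
            auc = dynamic_auc(1.0 - probs, T, delta, t_s, t_h, weighting)
            bs = brier_score(probs, T, delta, t_s, t_h, weighting)
            rows.append(
                {
                    "landmark": t_s,
                    "horizon": t_h,
                    "n_at_risk": int(np.sum(T > t_s)),
                    "auc": auc,
                    "brier": bs,
                }
            )
    return pd.DataFrame(rows)
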