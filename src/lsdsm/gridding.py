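"""Discretization of irregular longitudinal records onto the model grid.

The state space model runs on a regular grid with step ``dt``.  Interval
``j`` (1-based) covers ``[(j-1)dt, j*dt)``; a patient followed to time
``T`` (event or censoring) occupies ``m = ceil(T/dt)`` intervals.  Each
interval contributes an exposure ``tau_j`` (``dt`` for full intervals,
``T - (m-1)dt`` for the last partial one, so that ``sum(tau) == T``) and
an event indicator ``delta_bar_j`` which is 1 only in the final interval
of a patient who experienced the event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GriddedPatient",
    "grid_patient",
    "normalize_biomarker",
    "grid_cohort",
]


@dataclass
class GriddedPatient:
    """One patient's discretized longitudinal record and survival outcome."""

    patient_id: object
    omega: np.ndarray          # baseline covariates (m_omega,)
    dt: float
    y: np.ndarray              # (m, m_y) with NaN in missing cells
    observed_mask: np.ndarray  # (m, m_y) boolean
    T: float                   # event/censoring time
    delta: int                 # 1 = event, 0 = censored
    m: int                     # number of grid intervals
    tau: np.ndarray            # (m,) per-interval exposures
    delta_bar: np.ndarray      # (m,) interval event indicators

    def truncated(self, n_steps: int) -> "GriddedPatient":
        """Administratively truncate the record after ``n_steps`` intervals.

        Used to form landmark datasets: the patient is treated as
        censored at ``n_steps * dt`` with all later measurements removed.
        """
        if n_steps < 1 or n_steps > self.m:
            raise ValueError(
                f"n_steps must be in [1, {self.m}], got {n_steps}"
            )
        if n_steps == self.m:
            return self
        tau = np.full(n_steps, self.dt)
        return GriddedPatient(
            patient_id=self.patient_id,
            omega=self.omega,
            dt=self.dt,
            y=self.y[:n_steps].copy(),
            observed_mask=self.observed_mask[:n_steps].copy(),
            T=n_steps * self.dt,
            delta=0,
            m=n_steps,
            tau=tau,
            delta_bar=np.zeros(n_steps),
        )


def grid_patient(
    times,
    values,
    omega,
    T: float,
    delta: int,
    dt: float,
    patient_id=None,
    aggregate: str = "mean",
) -> GriddedPatient:
    """Bin irregular observations onto the regular ``dt`` grid.

    Each observation at time ``t`` lands in interval ``floor(t/dt) + 1``
    (an observation exactly at ``T`` goes to the last interval).  Multiple
    observations in a bin are averaged (``aggregate="mean"``) or the first
    is kept (``aggregate="first"``); empty bins are missing.

    Parameters
    ----------
    times : array-like of shape (n_obs,)
        Observation times in the unit of ``dt``, within ``[0, T]``.
    values : array-like of shape (n_obs, m_y)
        Biomarker rows; NaN entries denote missing components.
    """
    if T <= 0:
        raise ValueError(f"follow-up time T must be positive, got {T}")
    if dt <= 0:
        raise ValueError(f"grid step dt must be positive, got {dt}")
    times = np.asarray(times, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if times.size and values.shape[0] != times.size:
        raise ValueError("times and values rows must match")
    if times.size and (times.min() < 0 or times.max() > T):
        raise ValueError("observation times must lie in [0, T]")
    if aggregate not in ("mean", "first"):
        raise ValueError("aggregate must be 'mean' or 'first'")

    m = int(np.ceil(T / dt - 1e-12))
    m = max(m, 1)
    m_y = values.shape[1] if values.size else np.shape(values)[-1]

    y = np.full((m, m_y), np.nan)
    counts = np.zeros((m, m_y))
    if times.size:
        bins = np.minimum(np.floor(times / dt).astype(int), m - 1)
        if aggregate == "mean":
            sums = np.zeros((m, m_y))
            for b, row in zip(bins, values):
                obs = ~np.isnan(row)
                sums[b, obs] += row[obs]
                counts[b, obs] += 1
            with np.errstate(invalid="ignore"):
                y = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        else:
            for b, row in zip(bins, values):
                obs = ~np.isnan(row) & np.isnan(y[b])
                y[b, obs] = row[obs]
                counts[b, obs] += 1

    tau = np.full(m, dt)
    tau[-1] = T - (m - 1) * dt
    delta_bar = np.zeros(m)
    if delta:
        delta_bar[-1] = 1.0

    return GriddedPatient(
        patient_id=patient_id,
        omega=np.asarray(omega, dtype=float).ravel(),
        dt=float(dt),
        y=y,
        observed_mask=~np.isnan(y),
        T=float(T),
        delta=int(delta),
        m=m,
        tau=tau,
        delta_bar=delta_bar,
    )


def normalize_biomarker(values, cap: float, scale: float):
    """Truncate at ``cap`` and divide by ``scale``; NaN passes through.

    E.g. a walking distance recorded up to 1020 m, truncated at 1000 m
    and scaled by 1000, maps onto [0, 1] with 0.5 meaning 500 m.
    """
    if cap <= 0 or scale <= 0:
        raise ValueError("cap and scale must be positive")
    arr = np.asarray(values, dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("negative biomarker values encountered")
    return np.minimum(arr, cap) / scale


def grid_cohort(
    longitudinal: pd.DataFrame,
    baseline: pd.DataFrame,
    survival: pd.DataFrame,
    dt: float,
    aggregate: str = "mean",
    add_intercept: bool = False,
) -> list[GriddedPatient]:
    """Grid a long-format cohort into a list of :class:`GriddedPatient`.

    ``longitudinal`` has columns ``patient_id, time, <biomarker...>``;
    ``baseline`` has ``patient_id, <covariate...>``; ``survival`` has
    ``patient_id, time, event``.  Every patient in ``survival`` must be
    present in ``baseline``; longitudinal rows for unknown patients are an
    error.  ``add_intercept`` prepends a constant-1 covariate column.
    """
    biomarkers = [c for c in longitudinal.columns if c not in ("patient_id", "time")]
    covariates = [c for c in baseline.columns if c != "patient_id"]
    surv = survival.set_index("patient_id")
    base = baseline.set_index("patient_id")

    unknown = set(longitudinal["patient_id"]) - set(surv.index)
    if unknown:
        raise ValueError(
            f"longitudinal rows for patients missing from survival table: {sorted(unknown)!r}"
        )
    missing_base = set(surv.index) - set(base.index)
    if missing_base:
        raise ValueError(
            f"patients missing from baseline table: {sorted(missing_base)!r}"
        )

    grouped = dict(tuple(longitudinal.groupby("patient_id")))
    patients = []
    for pid in surv.index:
        rows = grouped.get(pid)
        if rows is None:
            times = np.empty(0)
            vals = np.empty((0, len(biomarkers)))
        else:
            times = rows["time"].to_numpy(dtype=float)
            vals = rows[biomarkers].to_numpy(dtype=float)
        omega = base.loc[pid, covariates].to_numpy(dtype=float)
        if add_intercept:
            omega = np.concatenate([[1.0], omega])
        patients.append(
            grid_patient(
                times,
                vals,
                omega=omega,
                T=float(surv.loc[pid, "time"]),
                delta=int(surv.loc[pid, "event"]),
                dt=dt,
                patient_id=pid,
                aggregate=aggregate,
            )
        )
    return patients
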