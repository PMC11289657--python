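"""Survival-corrected Kalman filtering and RTS smoothing.

The forward pass is a Kalman filter whose measurement update is augmented
with the current interval's survival information.  The one-step posterior

    p(x_j | y_1:j, survival through interval j)
        propto  N(y_j^obs; C^obs x_j, V^oo)
              * exp(delta_bar_j eta_j - tau_j exp(eta_j))
              * N(x_j; mu_pred, Sigma_pred),        eta_j = gamma'omega + alpha'H x_j

is not Gaussian, so it is approximated by a Gaussian centred at its mode
(found by damped Newton-Raphson) with covariance the inverse negative
Hessian there (a Laplace approximation).  When ``alpha = 0`` the survival
factor does not depend on the state and the update collapses to the exact
Kalman measurement update.  The backward pass is the standard
Rauch-Tung-Striebel recursion run on the corrected filtered beliefs.

Everything is implemented over batched arrays (leading axis = patients)
so a whole cohort advances one grid step per call; the public single-
patient operations are thin views of the same kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .canonical import ModelParameters
from .gridding import GriddedPatient

__all__ = [
    "GaussianBelief",
    "NewtonConfig",
    "SmoothedMoments",
    "ObservationExpectations",
    "time_update",
    "survival_measurement_update",
    "rts_backward",
    "expected_observation_moments",
    "filter_patient",
    "smooth_patient",
    "FilterResult",
]


def _symmetrize(S):
    return (S + np.swapaxes(S, -1, -2)) / 2.0


@dataclass
class GaussianBelief:
    """A Gaussian state belief N(mu, Sigma)."""

    mu: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.Sigma = _symmetrize(
            np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        )


@dataclass
class NewtonConfig:
    """Inner Newton-Raphson settings for the Laplace posterior approximation."""

    max_iter: int = 100
    tol: float = 1e-8          # infinity-norm of the Newton step
    max_halvings: int = 10     # backtracking halvings per step
    jitter0: float = 1e-8      # initial Hessian jitter on non-PD failure
    jitter_max: float = 1e-2


class NewtonError(RuntimeError):
    """Inner Newton-Raphson failed to produce a valid Gaussian approximation."""


# ---------------------------------------------------------------------------
# batched linear algebra helpers (small m_x, many patients)
# ---------------------------------------------------------------------------

def _batch_inv(S, jitter0=0.0, jitter_max=1e-2):
    """Invert a stack of small SPD matrices, escalating jitter on failure."""
    S = _symmetrize(S)
    jitter = jitter0
    eye = np.eye(S.shape[-1])
    while True:
        try:
            out = np.linalg.inv(S + jitter * eye if jitter else S)
            if np.all(np.isfinite(out)):
                return _symmetrize(out)
        except np.linalg.LinAlgError:
            pass
        jitter = max(jitter * 10.0, 1e-10 if jitter == 0.0 else jitter * 10.0)
        if jitter > jitter_max:
            raise NewtonError("singular covariance: jitter escalation exhausted")


# ---------------------------------------------------------------------------
# time update (prediction)
# ---------------------------------------------------------------------------

def _time_update_arrays(mu, Sigma, params: ModelParameters):
    A = params.A
    W = params.W
    mu_p = mu @ A.T
    Sigma_p = _symmetrize(A @ Sigma @ A.T) + W
    return mu_p, Sigma_p


def time_update(belief: GaussianBelief, params: ModelParameters) -> GaussianBelief:
    """One-step-ahead prediction: mu' = A mu, Sigma' = A Sigma A' + G W_breve G'."""
    mu_p, Sigma_p = _time_update_arrays(belief.mu, belief.Sigma, params)
    return GaussianBelief(mu_p, Sigma_p)


# ---------------------------------------------------------------------------
# survival-corrected measurement update (batched Newton-Raphson / Laplace)
# ---------------------------------------------------------------------------

def _newton_correct(
    mu_p,            # (k, m_x) predicted means
    Sigma_p,         # (k, m_x, m_x) predicted covariances
    y_obs,           # (k, n_o) observed measurement components (pattern-shared)
    C_o,             # (n_o, m_x) rows of C for the observed components
    Voo_inv,         # (n_o, n_o)
    g,               # (k,) gamma' omega per patient
    a,               # (m_x,) H' alpha
    tau,             # (k,)
    delta_bar,       # (k,)
    cfg: NewtonConfig,
):
    """Laplace-approximate the survival-corrected posterior for one
    missingness pattern shared by ``k`` patients.

    Returns (mu_post, Sigma_post, n_iter, converged).
    """
    k, m_x = mu_p.shape
    P_inv = _batch_inv(Sigma_p, jitter_max=cfg.jitter_max)
    CtVi = C_o.T @ Voo_inv                      # (m_x, n_o)
    CtViC = CtVi @ C_o                          # (m_x, m_x)
    a_col = a.reshape(-1, 1)
    quad_const = a_col @ a_col.T                # (m_x, m_x)

    def eta(x):
        return g + x @ a

    def objective(x):
        d = x - mu_p
        quad_prior = -0.5 * np.einsum("ki,kij,kj->k", d, P_inv, d)
        if y_obs.shape[1]:
            r = y_obs - x @ C_o.T
            quad_meas = -0.5 * np.einsum("ki,ij,kj->k", r, Voo_inv, r)
        else:
            quad_meas = 0.0
        e = np.clip(eta(x), -700, 700)
        return quad_prior + quad_meas + delta_bar * e - tau * np.exp(e)

    x = mu_p.copy()
    f = objective(x)
    converged = np.zeros(k, dtype=bool)
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        e = np.clip(eta(x), -700, 700)
        h = tau * np.exp(e)                      # (k,)
        grad = -np.einsum("kij,kj->ki", P_inv, x - mu_p)
        if y_obs.shape[1]:
            grad += (y_obs - x @ C_o.T) @ CtVi.T
        grad += (delta_bar - h)[:, None] * a
        neg_hess = P_inv + CtViC + h[:, None, None] * quad_const
        try:
            step = np.linalg.solve(neg_hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            neg_hess = neg_hess + cfg.jitter0 * np.eye(m_x)
            step = np.linalg.solve(neg_hess, grad[..., None])[..., 0]
        # backtracking: halve the step where the objective does not improve
        scale = np.ones(k)
        for _ in range(cfg.max_halvings):
            x_new = x + scale[:, None] * step
            f_new = objective(x_new)
            bad = f_new < f - 1e-12
            if not np.any(bad):
                break
            scale[bad] *= 0.5
        x_new = x + scale[:, None] * step
        f = objective(x_new)
        converged = np.abs(scale[:, None] * step).max(axis=1) < cfg.tol
        x = x_new
        if np.all(converged):
            break

    e = np.clip(eta(x), -700, 700)
    h = tau * np.exp(e)
    neg_hess = P_inv + CtViC + h[:, None, None] * quad_const
    Sigma_post = _batch_inv(
        neg_hess, jitter0=0.0, jitter_max=cfg.jitter_max
    )
    return x, Sigma_post, n_iter, converged


def survival_measurement_update(
    pred: GaussianBelief,
    y_j,
    mask,
    omega,
    tau_j: float,
    delta_bar_j: float,
    params: ModelParameters,
    nr_config: NewtonConfig | None = None,
) -> GaussianBelief:
    """Correct a predicted belief with one interval's measurement and
    survival evidence.

    Unobserved measurement components (``mask`` False) contribute
    nothing; with ``tau_j = 0`` and nothing observed the posterior equals
    the prediction.
    """
    if tau_j < 0:
        raise ValueError("tau_j must be non-negative")
    cfg = nr_config or NewtonConfig()
    s = params.structure
    mask = np.asarray(mask, dtype=bool).ravel()
    y_j = np.asarray(y_j, dtype=float).ravel()
    obs = np.flatnonzero(mask)
    C_o = params.structure.C[obs, :]
    Voo = params.V[np.ix_(obs, obs)]
    Voo_inv = np.linalg.inv(Voo) if obs.size else np.zeros((0, 0))
    g = np.array([params.gamma @ np.asarray(omega, dtype=float).ravel()])
    a = s.H.T @ params.alpha
    mu, Sigma, n_iter, conv = _newton_correct(
        pred.mu[None, :],
        pred.Sigma[None, :, :],
        y_j[obs][None, :],
        C_o,
        Voo_inv,
        g,
        a,
        np.array([float(tau_j)]),
        np.array([float(delta_bar_j)]),
        cfg,
    )
    if not conv[0]:
        raise NewtonError(
            f"survival measurement update did not converge in {cfg.max_iter} iterations"
        )
    return GaussianBelief(mu[0], Sigma[0])


# ---------------------------------------------------------------------------
# cohort-level forward pass
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    """Forward-pass output for one patient: predicted and filtered beliefs."""

    pred_mu: np.ndarray     # (m, m_x)
    pred_Sigma: np.ndarray  # (m, m_x, m_x)
    filt_mu: np.ndarray
    filt_Sigma: np.ndarray
    nr_iters: int = 0


def _pack(patients: list[GriddedPatient], params: ModelParameters):
    n = len(patients)
    s = params.structure
    m = np.array([p.m for p in patients], dtype=int)
    m_max = int(m.max())
    y = np.full((n, m_max, s.m_y), np.nan)
    mask = np.zeros((n, m_max, s.m_y), dtype=bool)
    tau = np.zeros((n, m_max))
    db = np.zeros((n, m_max))
    omega = np.zeros((n, s.m_omega))
    for i, p in enumerate(patients):
        y[i, : p.m] = p.y
        mask[i, : p.m] = p.observed_mask
        tau[i, : p.m] = p.tau
        db[i, : p.m] = p.delta_bar
        omega[i] = p.omega
    return y, mask, tau, db, omega, m


def filter_cohort(
    patients: list[GriddedPatient],
    params: ModelParameters,
    nr_config: NewtonConfig | None = None,
):
    """Run the survival-corrected filter over a whole cohort.

    Returns packed arrays ``(pred_mu, pred_Sigma, filt_mu, filt_Sigma, m)``
    with leading patient axis and a step axis padded to the longest record.
    """
    cfg = nr_config or NewtonConfig()
    s = params.structure
    y, mask, tau, db, omega, m = _pack(patients, params)
    n, m_max, m_y = y.shape
    m_x = s.m_x

    pred_mu = np.zeros((n, m_max, m_x))
    pred_Sigma = np.zeros((n, m_max, m_x, m_x))
    filt_mu = np.zeros((n, m_max, m_x))
    filt_Sigma = np.zeros((n, m_max, m_x, m_x))

    g_all = omega @ params.gamma
    a = s.H.T @ params.alpha
    C = s.C
    V = params.V

    for j in range(m_max):
        active = np.flatnonzero(m > j)
        if j == 0:
            pm = np.broadcast_to(params.x1_bar, (active.size, m_x)).copy()
            pS = np.broadcast_to(params.W1_bar, (active.size, m_x, m_x)).copy()
        else:
            pm, pS = _time_update_arrays(
                filt_mu[active, j - 1], filt_Sigma[active, j - 1], params
            )
        pred_mu[active, j] = pm
        pred_Sigma[active, j] = pS

        # group by missingness pattern so each group shares C_o and V_oo
        patterns = mask[active, j]
        codes = patterns @ (1 << np.arange(m_y))
        for code in np.unique(codes):
            sel = codes == code
            idx = active[sel]
            obs = np.flatnonzero(patterns[np.argmax(sel)])
            C_o = C[obs, :]
            Voo_inv = (
                np.linalg.inv(V[np.ix_(obs, obs)]) if obs.size else np.zeros((0, 0))
            )
            y_o = y[idx, j][:, obs] if obs.size else np.zeros((idx.size, 0))
            mu_c, Sig_c, _, conv = _newton_correct(
                pm[sel], pS[sel], y_o, C_o, Voo_inv,
                g_all[idx], a, tau[idx, j], db[idx, j], cfg,
            )
            if not np.all(conv):
                bad = [patients[i].patient_id for i in idx[~conv]]
                raise NewtonError(
                    f"filter correction failed to converge at step {j + 1} "
                    f"for patients {bad!r}"
                )
            filt_mu[idx, j] = mu_c
            filt_Sigma[idx, j] = Sig_c

    return pred_mu, pred_Sigma, filt_mu, filt_Sigma, m


def filter_patient(
    patient: GriddedPatient,
    params: ModelParameters,
    nr_config: NewtonConfig | None = None,
) -> FilterResult:
    """Survival-corrected forward pass for a single patient."""
    pm, pS, fm, fS, _ = filter_cohort([patient], params, nr_config)
    return FilterResult(pm[0], pS[0], fm[0], fS[0])


# ---------------------------------------------------------------------------
# RTS backward smoothing
# ---------------------------------------------------------------------------

@dataclass
class SmoothedMoments:
    """Smoothed posterior moments for one patient, feeding the M-step.

    ``lag_one[j]`` is Cov(x_{j+1}, x_j | all data) = Sigma_hat_{j+1} J_j',
    stored for j = 0..m-2.  Starred (reduced) quantities retain the
    leading ``m_y`` states of the canonical form.
    """

    mu_hat: np.ndarray        # (m, m_x)
    Sigma_hat: np.ndarray     # (m, m_x, m_x)
    J: np.ndarray             # (m-1, m_x, m_x) smoother gains
    lag_one: np.ndarray       # (m-1, m_x, m_x)
    m_y: int = field(default=0)

    @property
    def Ex(self) -> np.ndarray:
        return self.mu_hat

    @property
    def Exx(self) -> np.ndarray:
        return self.Sigma_hat + np.einsum(
            "ji,jk->jik", self.mu_hat, self.mu_hat
        )

    @property
    def Exx_lag(self) -> np.ndarray:
        """E[x_{j+1} x_j'] for j = 0..m-2."""
        return self.lag_one + np.einsum(
            "ji,jk->jik", self.mu_hat[1:], self.mu_hat[:-1]
        )

    # reduced (starred) variants: leading m_y rows of the full moments
    @property
    def Exx_star(self) -> np.ndarray:
        return self.Exx[:, : self.m_y, : self.m_y]

    @property
    def Exx_lag_star(self) -> np.ndarray:
        return self.Exx_lag[:, : self.m_y, :]


def _smooth_arrays(filt_mu, filt_Sigma, pred_mu, pred_Sigma, m, params):
    """Batched RTS recursion; returns smoothed means/covs, gains, lag-one covs."""
    n, m_max, m_x = filt_mu.shape
    A = params.A
    sm_mu = filt_mu.copy()
    sm_Sigma = filt_Sigma.copy()
    J = np.zeros((n, max(m_max - 1, 0), m_x, m_x))
    lag = np.zeros((n, max(m_max - 1, 0), m_x, m_x))
    for j in range(m_max - 2, -1, -1):
        active = np.flatnonzero(m > j + 1)
        if active.size == 0:
            continue
        P_pred_inv = _batch_inv(pred_Sigma[active, j + 1])
        Jj = filt_Sigma[active, j] @ A.T @ P_pred_inv
        sm_mu[active, j] = filt_mu[active, j] + np.einsum(
            "kij,kj->ki", Jj, sm_mu[active, j + 1] - pred_mu[active, j + 1]
        )
        sm_Sigma[active, j] = _symmetrize(
            filt_Sigma[active, j]
            + Jj
            @ (sm_Sigma[active, j + 1] - pred_Sigma[active, j + 1])
            @ np.swapaxes(Jj, -1, -2)
        )
        J[active, j] = Jj
        lag[active, j] = sm_Sigma[active, j + 1] @ np.swapaxes(Jj, -1, -2)
    return sm_mu, sm_Sigma, J, lag


def rts_backward(
    filtered: list[GaussianBelief],
    predicted: list[GaussianBelief],
    params: ModelParameters,
) -> SmoothedMoments:
    """Standard RTS backward pass from survival-corrected filtered beliefs.

    ``predicted[j]`` is the prior belief used at step j (so
    ``predicted[0]`` is the initial-state prior).
    """
    if len(filtered) != len(predicted) or not filtered:
        raise ValueError("filtered and predicted must be equal-length, non-empty")
    fm = np.stack([b.mu for b in filtered])[None]
    fS = np.stack([b.Sigma for b in filtered])[None]
    pm = np.stack([b.mu for b in predicted])[None]
    pS = np.stack([b.Sigma for b in predicted])[None]
    m = np.array([len(filtered)])
    sm_mu, sm_Sigma, J, lag = _smooth_arrays(fm, fS, pm, pS, m, params)
    return SmoothedMoments(
        mu_hat=sm_mu[0],
        Sigma_hat=sm_Sigma[0],
        J=J[0],
        lag_one=lag[0],
        m_y=params.structure.m_y,
    )


def smooth_patient(
    patient: GriddedPatient,
    params: ModelParameters,
    nr_config: NewtonConfig | None = None,
) -> SmoothedMoments:
    """Filter then smooth a single patient."""
    fr = filter_patient(patient, params, nr_config)
    filtered = [GaussianBelief(fr.filt_mu[j], fr.filt_Sigma[j]) for j in range(patient.m)]
    predicted = [GaussianBelief(fr.pred_mu[j], fr.pred_Sigma[j]) for j in range(patient.m)]
    return rts_backward(filtered, predicted, params)


# ---------------------------------------------------------------------------
# missing-measurement observation expectations
# ---------------------------------------------------------------------------

@dataclass
class ObservationExpectations:
    """Per-step expectations of the (partially missing) observation vector."""

    Ey: np.ndarray    # (m, m_y)
    Eyy: np.ndarray   # (m, m_y, m_y)
    Eyx: np.ndarray   # (m, m_y, m_x)


def expected_observation_moments(
    y_j,
    mask,
    smoothed_j: GaussianBelief,
    params: ModelParameters,
):
    """E[y], E[y y'], E[y x'] for one step under the smoothed state posterior.

    Missing components are imputed from the state posterior and the
    measurement-error covariance restricted to the observed components:
    with ``nabla = I - V Omega_o' (V^oo)^-1 Omega_o`` (zero on the observed
    block),

        E[y]    = y - nabla (y - C mu_hat)
        E[y y'] = I_m (nabla V + nabla C Sigma_hat C' nabla') I_m + E[y] E[y]'
        E[y x'] = nabla C Sigma_hat + E[y] E[x]'

    where ``I_m`` zeroes the observed rows/columns.
    """
    s = params.structure
    mask = np.asarray(mask, dtype=bool).ravel()
    y_j = np.asarray(y_j, dtype=float).ravel()
    mu, Sigma = smoothed_j.mu, smoothed_j.Sigma
    C, V = s.C, params.V
    m_y = s.m_y
    obs = np.flatnonzero(mask)

    nabla = np.eye(m_y)
    if obs.size:
        Omega = np.eye(m_y)[obs, :]
        Voo_inv = np.linalg.inv(V[np.ix_(obs, obs)])
        nabla = nabla - V @ Omega.T @ Voo_inv @ Omega
    I_m = np.diag((~mask).astype(float))

    y_fill = np.where(mask, y_j, 0.0)
    Ey = y_fill - nabla @ (y_fill - C @ mu)
    core = nabla @ V + nabla @ C @ Sigma @ C.T @ nabla.T
    Eyy = I_m @ core @ I_m + np.outer(Ey, Ey)
    Eyx = nabla @ C @ Sigma + np.outer(Ey, mu)
    return Ey, _symmetrize(Eyy), Eyx
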