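"""EM estimation of the joint state-space / proportional-hazards model.

The E-step runs the survival-corrected filter and RTS smoother for every
patient and pools the posterior moments into sufficient statistics.  The
M-step has closed forms for the state-space parameters

    x1_bar  = mean of smoothed initial states
    W1_bar  = mean E[x1 x1'] - x1_bar x1_bar'
    A_bar   = (sum E[x*_j x_{j-1}']) (sum E[x_{j-1} x_{j-1}'])^-1
    W_breve = residual second moment of the AR block (using updated A_bar)
    V       = residual second moment of the observation equation

(the starred moments are the leading ``m_y`` rows of the full ones, as
required by the canonical form, and the transition/initial blocks use the
updated ``x1_bar`` and ``A_bar`` inside their covariance updates), while
the survival coefficients maximize

    f(gamma, alpha) = sum_ij  delta_bar_ij (gamma'omega_i + alpha'H mu_ij)
                      - tau_ij exp(gamma'omega_i)
                        * exp(alpha'H mu_ij + alpha'H Sigma_ij H'alpha / 2)

by damped Newton-Raphson with analytic gradient and Hessian.  The outer
loop alternates the two until the largest absolute elementwise parameter
change drops below ``tol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .canonical import CanonicalStructure, ModelParameters
from .filtering import (
    NewtonConfig,
    SmoothedMoments,
    _smooth_arrays,
    _symmetrize,
    filter_cohort,
)
from .gridding import GriddedPatient

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "SufficientStatistics",
    "e_step",
    "expected_complete_loglik",
    "update_state_params",
    "update_survival_params",
    "initialize",
    "fit",
    "gaussian_observed_loglik",
]


@dataclass
class FitConfig:
    """EM loop settings.

    ``tol`` is the elementwise convergence threshold on the parameter
    change between iterations; ``max_iter`` caps the number of EM sweeps.
    ``fix_alpha`` freezes the state-association coefficients at zero, in
    which case the filter is an exact Kalman filter and EM is exact.
    """

    tol: float = 5e-4
    max_iter: int = 600
    nr_config: NewtonConfig = field(default_factory=NewtonConfig)
    surv_nr_max_iter: int = 100
    surv_nr_tol: float = 1e-6
    fix_alpha: bool = False
    fix_gamma: bool = False
    compute_q_trace: bool = True

    def __post_init__(self):
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


@dataclass
class SufficientStatistics:
    """Pooled E-step moments plus the per-step arrays for the survival block."""

    n: int
    sum_mu1: np.ndarray          # (m_x,)
    sum_Ex1x1: np.ndarray        # (m_x, m_x)
    S_lag_star: np.ndarray       # (m_y, m_x)   sum_{j>=2} E[x*_j x_{j-1}']
    S_prev: np.ndarray           # (m_x, m_x)   sum_{j>=2} E[x_{j-1} x_{j-1}']
    S_curr_star: np.ndarray      # (m_y, m_y)   sum_{j>=2} E[x*_j x*_j']
    n_trans: int                 # sum (m_i - 1)
    S_yy: np.ndarray             # (m_y, m_y)   sum_j E[y y']
    S_yx: np.ndarray             # (m_y, m_x)   sum_j E[y x']
    S_xx: np.ndarray             # (m_x, m_x)   sum_j E[x x']
    n_obs: int                   # sum m_i
    # survival-objective arrays, one row per patient-step
    surv_u: np.ndarray           # (N, m_alpha)  H mu_hat
    surv_S: np.ndarray           # (N, m_alpha, m_alpha)  H Sigma_hat H'
    surv_omega: np.ndarray       # (N, m_omega)
    surv_tau: np.ndarray         # (N,)
    surv_db: np.ndarray          # (N,)
    per_patient: list[SmoothedMoments] | None = None


def e_step(
    patients: list[GriddedPatient],
    params: ModelParameters,
    nr_config: NewtonConfig | None = None,
    keep_per_patient: bool = False,
) -> SufficientStatistics:
    """Run the corrected filter + RTS smoother and pool all M-step moments."""
    if not patients:
        raise ValueError("empty cohort")
    s = params.structure
    pred_mu, pred_Sigma, filt_mu, filt_Sigma, m = filter_cohort(
        patients, params, nr_config
    )
    sm_mu, sm_Sigma, J, lag = _smooth_arrays(
        filt_mu, filt_Sigma, pred_mu, pred_Sigma, m, params
    )
    n, m_max, m_x = sm_mu.shape
    m_y = s.m_y
    step_mask = np.arange(m_max)[None, :] < m[:, None]       # (n, m_max)
    trans_mask = step_mask[:, 1:]                            # step j>=2 exists

    Exx = sm_Sigma + np.einsum("nji,njk->njik", sm_mu, sm_mu)
    Exx_lag = lag + np.einsum("nji,njk->njik", sm_mu[:, 1:], sm_mu[:, :-1])

    sum_mu1 = sm_mu[:, 0].sum(axis=0)
    sum_Ex1x1 = Exx[:, 0].sum(axis=0)
    wt = trans_mask.astype(float)
    S_lag_star = np.einsum("nj,njik->ik", wt, Exx_lag[:, :, :m_y, :])
    S_prev = np.einsum("nj,njik->ik", wt, Exx[:, :-1])
    S_curr_star = np.einsum("nj,njik->ik", wt, Exx[:, 1:, :m_y, :m_y])
    n_trans = int(wt.sum())

    # observation expectations (missing-data corrections), pooled per
    # missingness pattern so each pattern shares its nabla operator
    S_yy = np.zeros((m_y, m_y))
    S_yx = np.zeros((m_y, m_x))
    S_xx = np.einsum("nj,njik->ik", step_mask.astype(float), Exx)
    y_pad = np.full((n, m_max, m_y), np.nan)
    mask_pad = np.zeros((n, m_max, m_y), dtype=bool)
    for i, p in enumerate(patients):
        y_pad[i, : p.m] = p.y
        mask_pad[i, : p.m] = p.observed_mask
    C, V = s.C, params.V
    cell_idx = np.nonzero(step_mask)
    cell_mask = mask_pad[cell_idx]                        # (N, m_y)
    codes = cell_mask @ (1 << np.arange(m_y))
    for code in np.unique(codes):
        sel = codes == code
        obs = np.flatnonzero(cell_mask[np.argmax(sel)])
        nabla = np.eye(m_y)
        if obs.size:
            Omega = np.eye(m_y)[obs, :]
            nabla -= V @ Omega.T @ np.linalg.inv(V[np.ix_(obs, obs)]) @ Omega
        miss_diag = np.diag((~cell_mask[np.argmax(sel)]).astype(float))
        ii, jj = cell_idx[0][sel], cell_idx[1][sel]
        Y = np.nan_to_num(y_pad[ii, jj])
        MU = sm_mu[ii, jj]
        Sig_sum = sm_Sigma[ii, jj].sum(axis=0)
        Ey = Y - (Y - MU @ C.T) @ nabla.T
        core = sel.sum() * (nabla @ V) + nabla @ C @ Sig_sum @ C.T @ nabla.T
        S_yy += miss_diag @ core @ miss_diag + Ey.T @ Ey
        S_yx += nabla @ C @ Sig_sum + Ey.T @ MU
    S_yy = _symmetrize(S_yy)
    n_obs = int(m.sum())

    H = s.H
    flat_idx = np.nonzero(step_mask)
    surv_u = sm_mu[flat_idx] @ H.T
    surv_S = np.einsum("ai,nij,bj->nab", H, sm_Sigma[flat_idx], H)
    omegas = np.stack([p.omega for p in patients])
    surv_omega = omegas[flat_idx[0]]
    taus = np.zeros((n, m_max))
    dbs = np.zeros((n, m_max))
    for i, p in enumerate(patients):
        taus[i, : p.m] = p.tau
        dbs[i, : p.m] = p.delta_bar
    surv_tau = taus[flat_idx]
    surv_db = dbs[flat_idx]

    per_patient = None
    if keep_per_patient:
        per_patient = [
            SmoothedMoments(
                mu_hat=sm_mu[i, : p.m],
                Sigma_hat=sm_Sigma[i, : p.m],
                J=J[i, : p.m - 1],
                lag_one=lag[i, : p.m - 1],
                m_y=m_y,
            )
            for i, p in enumerate(patients)
        ]

    return SufficientStatistics(
        n=n,
        sum_mu1=sum_mu1,
        sum_Ex1x1=sum_Ex1x1,
        S_lag_star=S_lag_star,
        S_prev=S_prev,
        S_curr_star=S_curr_star,
        n_trans=n_trans,
        S_yy=S_yy,
        S_yx=S_yx,
        S_xx=S_xx,
        n_obs=n_obs,
        surv_u=surv_u,
        surv_S=surv_S,
        surv_omega=surv_omega,
        surv_tau=surv_tau,
        surv_db=surv_db,
        per_patient=per_patient,
    )


# ---------------------------------------------------------------------------
# expected complete-data log likelihood (Q function)
# ---------------------------------------------------------------------------

def _survival_objective_terms(stats: SufficientStatistics, gamma, alpha):
    lin = stats.surv_omega @ gamma + stats.surv_u @ alpha
    quad = 0.5 * np.einsum("a,nab,b->n", alpha, stats.surv_S, alpha)
    expo = stats.surv_tau * np.exp(np.clip(lin + quad, -700, 700))
    return lin, expo


def survival_objective(stats: SufficientStatistics, gamma, alpha) -> float:
    """The survival block f(gamma, alpha) of the expected complete-data
    log likelihood, with the Gaussian exponential moment of the hazard."""
    lin, expo = _survival_objective_terms(stats, gamma, alpha)
    return float(np.sum(stats.surv_db * lin - expo))


def expected_complete_loglik(stats: SufficientStatistics, theta: ModelParameters) -> float:
    """Q(theta): survival + measurement + initial-state + transition blocks
    (additive constants dropped).  The transition and initial blocks use
    the canonical (reduced) and full covariances respectively."""
    s = theta.structure
    m_y, C = s.m_y, s.C
    q = survival_objective(stats, theta.gamma, theta.alpha)

    V_inv = np.linalg.inv(theta.V)
    meas_quad = (
        stats.S_yy
        - stats.S_yx @ C.T
        - C @ stats.S_yx.T
        + C @ stats.S_xx @ C.T
    )
    sign, logdet_V = np.linalg.slogdet(theta.V)
    q += -0.5 * (stats.n_obs * logdet_V + np.trace(V_inv @ meas_quad))

    W1_inv = np.linalg.inv(theta.W1_bar)
    x1 = theta.x1_bar
    init_quad = (
        stats.sum_Ex1x1
        - np.outer(stats.sum_mu1, x1)
        - np.outer(x1, stats.sum_mu1)
        + stats.n * np.outer(x1, x1)
    )
    sign, logdet_W1 = np.linalg.slogdet(theta.W1_bar)
    q += -0.5 * (stats.n * logdet_W1 + np.trace(W1_inv @ init_quad))

    Wb_inv = np.linalg.inv(theta.W_breve)
    Ab = theta.A_bar
    trans_quad = (
        stats.S_curr_star
        - stats.S_lag_star @ Ab.T
        - Ab @ stats.S_lag_star.T
        + Ab @ stats.S_prev @ Ab.T
    )
    sign, logdet_Wb = np.linalg.slogdet(theta.W_breve)
    q += -0.5 * (stats.n_trans * logdet_Wb + np.trace(Wb_inv @ trans_quad))
    return float(q)


# ---------------------------------------------------------------------------
# M-step: closed-form state-space updates
# ---------------------------------------------------------------------------

_GRAM_COND_MAX = 1e12
_GRAM_JITTER = 1e-10


def update_state_params(stats: SufficientStatistics, structure: CanonicalStructure):
    """Closed-form maximizers of the state-space blocks of Q.

    Returns ``(x1_bar, W1_bar, A_bar, W_breve, V)``.  ``W1_bar`` uses the
    updated ``x1_bar`` and ``W_breve`` the updated ``A_bar``.
    """
    if stats.n_trans < 1:
        raise ValueError("need at least one transition (sum m_i >= 2)")
    C = structure.C
    x1_bar = stats.sum_mu1 / stats.n
    W1_bar = _symmetrize(stats.sum_Ex1x1 / stats.n - np.outer(x1_bar, x1_bar))

    gram = stats.S_prev.copy()
    if np.linalg.cond(gram) > _GRAM_COND_MAX:
        gram = gram + _GRAM_JITTER * np.eye(gram.shape[0])
    A_bar = np.linalg.solve(gram.T, stats.S_lag_star.T).T

    W_breve = _symmetrize(
        (
            stats.S_curr_star
            - stats.S_lag_star @ A_bar.T
            - A_bar @ stats.S_lag_star.T
            + A_bar @ stats.S_prev @ A_bar.T
        )
        / stats.n_trans
    )
    V = _symmetrize(
        (
            stats.S_yy
            - stats.S_yx @ C.T
            - C @ stats.S_yx.T
            + C @ stats.S_xx @ C.T
        )
        / stats.n_obs
    )
    return x1_bar, W1_bar, A_bar, W_breve, V


# ---------------------------------------------------------------------------
# M-step: Newton-Raphson survival update
# ---------------------------------------------------------------------------

class SurvivalUpdateError(RuntimeError):
    pass


def survival_grad_hess(stats: SufficientStatistics, gamma, alpha):
    """Analytic gradient and Hessian of f(gamma, alpha).

    With E_r = tau_r exp(gamma'omega_r + alpha'u_r + alpha'S_r alpha/2)
    and v_r = u_r + S_r alpha:

        df/dgamma = sum (db_r - E_r) omega_r
        df/dalpha = sum db_r u_r - E_r v_r
        H_gg = -sum E_r omega_r omega_r'
        H_ga = -sum E_r omega_r v_r'
        H_aa = -sum E_r (v_r v_r' + S_r)
    """
    _, expo = _survival_objective_terms(stats, gamma, alpha)
    v = stats.surv_u + np.einsum("nab,b->na", stats.surv_S, alpha)
    g_gamma = stats.surv_omega.T @ (stats.surv_db - expo)
    g_alpha = stats.surv_u.T @ stats.surv_db - v.T @ expo
    H_gg = -np.einsum("n,na,nb->ab", expo, stats.surv_omega, stats.surv_omega)
    H_ga = -np.einsum("n,na,nb->ab", expo, stats.surv_omega, v)
    H_aa = -np.einsum("n,na,nb->ab", expo, v, v) - np.einsum(
        "n,nab->ab", expo, stats.surv_S
    )
    grad = np.concatenate([g_gamma, g_alpha])
    hess = np.block([[H_gg, H_ga], [H_ga.T, H_aa]])
    return grad, hess


def update_survival_params(
    stats: SufficientStatistics,
    gamma0,
    alpha0,
    max_iter: int = 100,
    tol: float = 1e-6,
    fix_alpha: bool = False,
    fix_gamma: bool = False,
):
    """Maximize f(gamma, alpha) by damped Newton-Raphson from a warm start.

    Raises :class:`SurvivalUpdateError` on degenerate data (no events with
    a free intercept drives coefficients to -inf) or non-convergence.
    """
    gamma = np.asarray(gamma0, dtype=float).copy()
    alpha = np.asarray(alpha0, dtype=float).copy()
    m_g, m_a = gamma.size, alpha.size
    if stats.surv_db.sum() == 0 and not (fix_gamma and fix_alpha):
        raise SurvivalUpdateError(
            "no events in the cohort: the survival objective is maximized "
            "at -infinity; survival coefficients are not estimable"
        )
    free = np.concatenate(
        [np.full(m_g, not fix_gamma), np.full(m_a, not fix_alpha)]
    ).astype(bool)
    if not free.any():
        return gamma, alpha

    theta = np.concatenate([gamma, alpha])
    f_old = survival_objective(stats, theta[:m_g], theta[m_g:])
    for _ in range(max_iter):
        grad, hess = survival_grad_hess(stats, theta[:m_g], theta[m_g:])
        grad_f = grad[free]
        if np.max(np.abs(grad_f)) < tol:
            return theta[:m_g], theta[m_g:]
        hess_f = hess[np.ix_(free, free)]
        try:
            step = np.linalg.solve(hess_f, -grad_f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess_f, -grad_f, rcond=None)[0]
        if step @ grad_f < 0:       # not an ascent direction: fall back to gradient
            step = grad_f / max(np.max(np.abs(grad_f)), 1.0)
        scale = 1.0
        for _ in range(30):
            theta_new = theta.copy()
            theta_new[free] = theta[free] + scale * step
            f_new = survival_objective(stats, theta_new[:m_g], theta_new[m_g:])
            if f_new >= f_old - 1e-12:
                break
            scale *= 0.5
        else:
            raise SurvivalUpdateError("no ascent found in survival Newton-Raphson")
        theta, f_old = theta_new, f_new
    grad, _ = survival_grad_hess(stats, theta[:m_g], theta[m_g:])
    if np.max(np.abs(grad[free])) < 10 * tol:
        return theta[:m_g], theta[m_g:]
    raise SurvivalUpdateError(
        f"survival Newton-Raphson did not converge in {max_iter} iterations "
        f"(gradient inf-norm {np.max(np.abs(grad[free])):.2e})"
    )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(
    patients: list[GriddedPatient],
    structure: CanonicalStructure,
) -> ModelParameters:
    """Default data-driven starting values.

    Initial-state mean/covariance from the first observed measurement of
    each patient (replicated across AR lags), a stable persistence
    transition (spectral radius < 1), disturbance and measurement
    variances each at half the pooled variance of first differences, and
    zero survival coefficients.
    """
    if not patients:
        raise ValueError("empty cohort")
    m_y, M, m_x = structure.m_y, structure.M, structure.m_x
    firsts = []
    diffs = []
    for p in patients:
        row = np.full(m_y, np.nan)
        for k in range(m_y):
            obs = np.flatnonzero(p.observed_mask[:, k])
            if obs.size:
                row[k] = p.y[obs[0], k]
                vals = p.y[obs, k]
                if vals.size > 1:
                    diffs.extend(np.diff(vals).tolist())
        firsts.append(row)
    firsts = np.asarray(firsts)
    if np.all(np.isnan(firsts)):
        raise ValueError("no observed measurements anywhere in the cohort")
    y0_mean = np.nanmean(firsts, axis=0)
    y0_mean = np.where(np.isnan(y0_mean), 0.0, y0_mean)
    with np.errstate(invalid="ignore"):
        y0_var = np.nanvar(firsts, axis=0)
    y0_var = np.where(np.isnan(y0_var) | (y0_var < 1e-3), 1.0, y0_var)

    x1_bar = np.tile(y0_mean, M)
    W1_bar = np.kron(np.eye(M), np.diag(y0_var)) + 1e-3 * np.eye(m_x)

    A_bar = np.zeros((m_y, m_x))
    A_bar[:, :m_y] = 0.9 * np.eye(m_y)

    diff_var = float(np.var(diffs)) if len(diffs) > 1 else 1.0
    diff_var = max(diff_var, 1e-4)
    W_breve = 0.5 * diff_var * np.eye(m_y)
    V = 0.5 * diff_var * np.eye(m_y)

    m_omega = patients[0].omega.size
    if m_omega != structure.m_omega:
        raise ValueError(
            f"structure expects {structure.m_omega} baseline covariates, "
            f"patients carry {m_omega}"
        )
    return ModelParameters(
        structure=structure,
        A_bar=A_bar,
        W_breve=W_breve,
        V=V,
        x1_bar=x1_bar,
        W1_bar=W1_bar,
        gamma=np.zeros(structure.m_omega),
        alpha=np.zeros(structure.m_alpha),
    )


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """EM output: estimates, convergence state and per-iteration trace."""

    theta_hat: ModelParameters
    n_iter: int
    converged: bool
    q_trace: list[float]
    change_trace: list[float]
    diagnostics: dict = field(default_factory=dict)


def fit(
    patients: list[GriddedPatient],
    structure: CanonicalStructure,
    config: FitConfig | None = None,
    theta0: ModelParameters | None = None,
) -> FitResult:
    """Run EM to convergence (elementwise parameter change below ``tol``)."""
    config = config or FitConfig()
    theta = (theta0 or initialize(patients, structure)).copy()
    q_trace: list[float] = []
    change_trace: list[float] = []
    converged = False
    k = 0
    for k in range(1, config.max_iter + 1):
        try:
            stats = e_step(patients, theta, config.nr_config)
            x1_bar, W1_bar, A_bar, W_breve, V = update_state_params(stats, structure)
            gamma, alpha = update_survival_params(
                stats,
                theta.gamma,
                theta.alpha,
                max_iter=config.surv_nr_max_iter,
                tol=config.surv_nr_tol,
                fix_alpha=config.fix_alpha,
                fix_gamma=config.fix_gamma,
            )
        except Exception as exc:
            raise RuntimeError(f"EM failed at iteration {k}: {exc}") from exc
        theta_new = ModelParameters(
            structure=structure,
            A_bar=A_bar,
            W_breve=W_breve,
            V=V,
            x1_bar=x1_bar,
            W1_bar=W1_bar,
            gamma=gamma,
            alpha=alpha,
        )
        if config.compute_q_trace:
            q_trace.append(expected_complete_loglik(stats, theta_new))
        change = theta_new.max_abs_diff(theta)
        change_trace.append(change)
        logger.info(
            "EM iteration %d: max parameter change %.3e%s",
            k, change,
            f", Q = {q_trace[-1]:.6f}" if q_trace else "",
        )
        theta = theta_new
        if change < config.tol:
            converged = True
            break
    return FitResult(
        theta_hat=theta,
        n_iter=k,
        converged=converged,
        q_trace=q_trace,
        change_trace=change_trace,
        diagnostics={"final_change": change_trace[-1] if change_trace else np.nan},
    )


# ---------------------------------------------------------------------------
# exact observed-data log likelihood (alpha = 0 case)
# ---------------------------------------------------------------------------

def gaussian_observed_loglik(patients: list[GriddedPatient], params: ModelParameters) -> float:
    """Exact observed-data log likelihood when ``alpha = 0``.

    The survival factor then separates from the states, so the
    longitudinal part is the Kalman prediction-error decomposition over
    the observed measurement components and the survival part is a
    piecewise-exponential likelihood in ``gamma`` alone.
    """
    if np.any(params.alpha != 0):
        raise ValueError("exact observed-data likelihood requires alpha = 0")
    s = params.structure
    C, V = s.C, params.V
    ll = 0.0
    for p in patients:
        mu, Sigma = params.x1_bar.copy(), params.W1_bar.copy()
        for j in range(p.m):
            if j > 0:
                mu = params.A @ mu
                Sigma = _symmetrize(params.A @ Sigma @ params.A.T) + params.W
            obs = np.flatnonzero(p.observed_mask[j])
            if obs.size:
                C_o = C[obs, :]
                S = C_o @ Sigma @ C_o.T + V[np.ix_(obs, obs)]
                r = p.y[j, obs] - C_o @ mu
                sign, logdet = np.linalg.slogdet(S)
                S_inv = np.linalg.inv(S)
                ll += -0.5 * (
                    obs.size * np.log(2 * np.pi) + logdet + r @ S_inv @ r
                )
                K = Sigma @ C_o.T @ S_inv
                mu = mu + K @ r
                Sigma = _symmetrize((np.eye(s.m_x) - K @ C_o) @ Sigma)
        eta = params.gamma @ p.omega
        ll += p.delta * eta - np.sum(p.tau) * np.exp(eta)
    return float(ll)
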