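import numpy as np
import pytest
from scipy.optimize import minimize

from lsdsm.canonical import ModelParameters, build_canonical_structure
from lsdsm.em import (
    FitConfig,
    SufficientStatistics,
    SurvivalUpdateError,
    e_step,
    expected_complete_loglik,
    fit,
    gaussian_observed_loglik,
    initialize,
    survival_grad_hess,
    survival_objective,
    update_state_params,
    update_survival_params,
)
from lsdsm.gridding import grid_patient
from lsdsm.simulate import SimConfig, simulate_cohort

from .oracles import joint_gaussian_smoother, ssm_em_iteration


def _ar1_model(A=0.8, W=0.25, V=0.2, x1=0.5, W1=1.0, gamma=(-1.2,), alpha=0.0):
    s = build_canonical_structure(m_y=1, M=1, m_omega=len(gamma))
    return ModelParameters(
        structure=s, A_bar=[[A]], W_breve=[[W]], V=[[V]],
        x1_bar=[x1], W1_bar=[[W1]], gamma=list(gamma), alpha=[alpha],
    )


def _simulated_ar1_patients(n=25, m=8, seed=0, gamma=-1.2):
    """Fully observed AR(1) records with survival outcomes independent of
    the states (consistent with alpha = 0)."""
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n):
        x = np.zeros(m)
        x[0] = 0.5 + rng.normal()
        for j in range(1, m):
            x[j] = 0.8 * x[j - 1] + 0.5 * rng.normal()
        y = x + np.sqrt(0.2) * rng.normal(size=m)
        T_event = rng.exponential(1.0 / np.exp(gamma))
        T = float(min(T_event, m))
        delta = int(T_event < m)
        mi = max(int(np.ceil(T - 1e-12)), 1)
        patients.append(
            grid_patient(
                np.arange(mi, dtype=float), y[:mi, None],
                omega=[1.0], T=T, delta=delta, dt=1.0, patient_id=i,
            )
        )
    return patients


class TestEStep:
    def test_empty_cohort_rejected(self, ar1_params):
        with pytest.raises(ValueError, match="empty"):
            e_step([], ar1_params)

    def test_single_step_patient_has_no_lagged_sums(self, ar1_params):
        p = grid_patient([0.0], [[1.0]], omega=[1.0], T=0.7, delta=1, dt=1.0)
        stats = e_step([p], ar1_params)
        assert stats.n_trans == 0
        assert stats.n_obs == 1
        np.testing.assert_array_equal(stats.S_prev, 0.0)

    def test_alpha_zero_matches_plain_ssm_estep(self):
        """With alpha=0 and full observation, pooled moments equal those of
        an independently coded linear-Gaussian E-step."""
        theta = _ar1_model()
        patients = _simulated_ar1_patients(n=6, m=5, seed=1)
        stats = e_step(patients, theta)
        A = theta.A
        sum_mu1 = np.zeros(1)
        sum_E11 = np.zeros((1, 1))
        S_lag = np.zeros((1, 1))
        S_prev = np.zeros((1, 1))
        for p in patients:
            ys = [p.y[j] for j in range(p.m)]
            means, covs, lags = joint_gaussian_smoother(
                ys, A, theta.W, theta.structure.C, theta.V,
                theta.x1_bar, theta.W1_bar,
            )
            sum_mu1 += means[0]
            sum_E11 += covs[0] + np.outer(means[0], means[0])
            for j in range(1, p.m):
                S_lag += lags[j - 1] + np.outer(means[j], means[j - 1])
                S_prev += covs[j - 1] + np.outer(means[j - 1], means[j - 1])
        np.testing.assert_allclose(stats.sum_mu1, sum_mu1, atol=1e-8)
        np.testing.assert_allclose(stats.sum_Ex1x1, sum_E11, atol=1e-8)
        np.testing.assert_allclose(stats.S_lag_star, S_lag, atol=1e-8)
        np.testing.assert_allclose(stats.S_prev, S_prev, atol=1e-8)

    def test_pooled_sums_permutation_invariant(self, ar2_params):
        cohort = simulate_cohort(config=SimConfig(n=12, seed=5)).patients
        s1 = e_step(cohort, ar2_params)
        s2 = e_step(cohort[::-1], ar2_params)
        np.testing.assert_allclose(s1.S_prev, s2.S_prev, atol=1e-9)
        np.testing.assert_allclose(s1.S_yy, s2.S_yy, atol=1e-9)


class TestStateUpdates:
    def test_single_patient_single_step(self, ar1_params):
        """One patient, one interval: the initial-state updates collapse to
        that patient's smoothed moments; the transition update is undefined."""
        p = grid_patient([0.0], [[1.0]], omega=[1.0], T=0.7, delta=0, dt=1.0)
        stats = e_step([p], ar1_params)
        np.testing.assert_allclose(stats.sum_mu1 / stats.n, stats.sum_mu1)
        with pytest.raises(ValueError, match="transition"):
            update_state_params(stats, ar1_params.structure)

    def test_initial_state_update_equals_smoothed_first_moments(self, ar1_params):
        patients = _simulated_ar1_patients(n=4, m=4, seed=2)
        stats = e_step(patients, ar1_params)
        x1, W1, *_ = update_state_params(stats, ar1_params.structure)
        np.testing.assert_allclose(x1, stats.sum_mu1 / stats.n)
        np.testing.assert_allclose(
            W1, stats.sum_Ex1x1 / stats.n - np.outer(x1, x1), atol=1e-12
        )

    def test_transition_update_is_least_squares_on_deterministic_states(self):
        """With degenerate posteriors (Sigma_hat = 0) the A update reduces
        to the OLS regression of x_j on x_{j-1}."""
        rng = np.random.default_rng(7)
        seq = rng.normal(size=(10, 2))
        s = build_canonical_structure(m_y=1, M=2, m_omega=1)
        S_lag = np.zeros((1, 2))
        S_prev = np.zeros((2, 2))
        S_curr = np.zeros((1, 1))
        for j in range(1, 10):
            S_lag += np.outer(seq[j, :1], seq[j - 1])
            S_prev += np.outer(seq[j - 1], seq[j - 1])
            S_curr += np.outer(seq[j, :1], seq[j, :1])
        stats = SufficientStatistics(
            n=1, sum_mu1=seq[0], sum_Ex1x1=np.outer(seq[0], seq[0]),
            S_lag_star=S_lag, S_prev=S_prev, S_curr_star=S_curr, n_trans=9,
            S_yy=np.eye(1), S_yx=np.zeros((1, 2)), S_xx=np.eye(2), n_obs=10,
            surv_u=np.zeros((0, 1)), surv_S=np.zeros((0, 1, 1)),
            surv_omega=np.zeros((0, 1)), surv_tau=np.zeros(0), surv_db=np.zeros(0),
        )
        _, _, A_bar, W_breve, _ = update_state_params(stats, s)
        A_ols = np.linalg.lstsq(seq[:-1], seq[1:, 0], rcond=None)[0]
        np.testing.assert_allclose(A_bar.ravel(), A_ols, atol=1e-10)

    def test_q_stationary_at_state_updates(self, ar1_params):
        """Numerical gradient of Q with respect to each state parameter
        vanishes at the closed-form update."""
        patients = _simulated_ar1_patients(n=10, m=6, seed=3)
        stats = e_step(patients, ar1_params)
        x1, W1, A_bar, W_breve, V = update_state_params(stats, ar1_params.structure)
        theta = ModelParameters(
            structure=ar1_params.structure, A_bar=A_bar, W_breve=W_breve, V=V,
            x1_bar=x1, W1_bar=W1, gamma=ar1_params.gamma, alpha=ar1_params.alpha,
        )
        q0 = expected_complete_loglik(stats, theta)
        h = 1e-6
        for field in ("A_bar", "x1_bar"):
            arr = getattr(theta, field)
            for idx in np.ndindex(arr.shape):
                pert = theta.copy()
                getattr(pert, field)[idx] += h
                qp = expected_complete_loglik(stats, pert)
                getattr(pert, field)[idx] -= 2 * h
                qm = expected_complete_loglik(stats, pert)
                assert abs((qp - qm) / (2 * h)) < 1e-4 * max(abs(q0), 1.0)

    def test_q_additivity_over_patients(self, ar1_params):
        patients = _simulated_ar1_patients(n=5, m=5, seed=4)
        s1 = e_step(patients, ar1_params)
        s2 = e_step(patients + patients, ar1_params)
        q1 = expected_complete_loglik(s1, ar1_params)
        q2 = expected_complete_loglik(s2, ar1_params)
        assert q2 == pytest.approx(2 * q1, rel=1e-10)


class TestSurvivalUpdate:
    def _stats(self, seed=0, n_steps=400, m_alpha=1, zero_Sigma=False):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=(n_steps, m_alpha))
        S = np.zeros((n_steps, m_alpha, m_alpha))
        if not zero_Sigma:
            L = rng.normal(size=(n_steps, m_alpha, m_alpha)) * 0.2
            S = L @ np.swapaxes(L, -1, -2)
        omega = np.column_stack([np.ones(n_steps), rng.normal(size=n_steps)])
        tau = np.full(n_steps, 1.0)
        eta = -1.5 + 0.5 * omega[:, 1] - 0.6 * u[:, 0]
        db = (rng.uniform(size=n_steps) < 1 - np.exp(-np.exp(eta))).astype(float)
        return SufficientStatistics(
            n=1, sum_mu1=np.zeros(1), sum_Ex1x1=np.eye(1),
            S_lag_star=np.zeros((1, 1)), S_prev=np.eye(1),
            S_curr_star=np.eye(1), n_trans=1,
            S_yy=np.eye(1), S_yx=np.zeros((1, 1)), S_xx=np.eye(1), n_obs=1,
            surv_u=u, surv_S=S, surv_omega=omega, surv_tau=tau, surv_db=db,
        )

    def test_gradient_matches_finite_differences(self):
        stats = self._stats(seed=1)
        gamma = np.array([-1.0, 0.3])
        alpha = np.array([-0.4])
        grad, hess = survival_grad_hess(stats, gamma, alpha)
        theta = np.concatenate([gamma, alpha])
        h = 1e-6
        for k in range(3):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (
                survival_objective(stats, tp[:2], tp[2:])
                - survival_objective(stats, tm[:2], tm[2:])
            ) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-6)
        # Hessian check via gradient differences
        for k in range(3):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            gp, _ = survival_grad_hess(stats, tp[:2], tp[2:])
            gm, _ = survival_grad_hess(stats, tm[:2], tm[2:])
            np.testing.assert_allclose(
                hess[:, k], (gp - gm) / (2 * h), rtol=1e-4, atol=1e-5
            )

    def test_returns_stationary_point(self):
        stats = self._stats(seed=2)
        gamma, alpha = update_survival_params(
            stats, np.zeros(2), np.zeros(1)
        )
        grad, _ = survival_grad_hess(stats, gamma, alpha)
        assert np.max(np.abs(grad)) < 1e-5

    def test_matches_generic_optimizer_with_degenerate_posteriors(self):
        """With all Sigma_hat = 0 the objective is a plain piecewise-
        exponential PH log likelihood; a derivative-free optimizer must
        find the same optimum."""
        stats = self._stats(seed=3, zero_Sigma=True)
        gamma, alpha = update_survival_params(stats, np.zeros(2), np.zeros(1))

        def neg_f(v):
            return -survival_objective(stats, v[:2], v[2:])

        res = minimize(neg_f, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
        np.testing.assert_allclose(
            np.concatenate([gamma, alpha]), res.x, atol=1e-4
        )

    def test_no_events_is_degenerate(self):
        stats = self._stats(seed=4)
        stats.surv_db[:] = 0.0
        with pytest.raises(SurvivalUpdateError, match="no events"):
            update_survival_params(stats, np.zeros(2), np.zeros(1))


class TestInitialize:
    def test_constant_cohort_mean(self):
        s = build_canonical_structure(m_y=1, M=2, m_omega=1)
        patients = [
            grid_patient([0.0, 1.0], [[3.0], [3.0]], omega=[1.0], T=2.0,
                         delta=0, dt=1.0)
            for _ in range(4)
        ]
        theta = initialize(patients, s)
        np.testing.assert_allclose(theta.x1_bar, [3.0, 3.0])

    def test_initial_transition_is_stable(self, small_cohort):
        s = build_canonical_structure(m_y=1, M=2, m_omega=2)
        theta = initialize(small_cohort.patients, s)
        assert np.max(np.abs(np.linalg.eigvals(theta.A))) < 1.0

    def test_no_observations_rejected(self):
        s = build_canonical_structure(m_y=1, M=1, m_omega=1)
        p = grid_patient([], np.empty((0, 1)), omega=[1.0], T=2.0, delta=0, dt=1.0)
        with pytest.raises(ValueError, match="no observed"):
            initialize([p], s)


class TestFit:
    def test_single_iteration_boundary(self, small_cohort):
        s = build_canonical_structure(m_y=1, M=2, m_omega=2)
        res = fit(small_cohort.patients, s, FitConfig(tol=1e9, max_iter=1))
        assert res.n_iter == 1 and res.converged

    def test_alpha_frozen_matches_plain_ssm_em(self):
        """alpha fixed at 0: the state-parameter EM path must coincide with
        an independently coded Shumway-Stoffer iteration."""
        patients = _simulated_ar1_patients(n=8, m=5, seed=6)
        s = build_canonical_structure(m_y=1, M=1, m_omega=1)
        theta = _ar1_model()
        # one EM iteration via the package
        res = fit(
            patients, s,
            FitConfig(tol=1e12, max_iter=1, fix_alpha=True),
            theta0=theta,
        )
        # oracle iteration on the same data
        ys = [[p.y[j] for j in range(p.m)] for p in patients]
        x1_o, W1_o, A_o, W_o, V_o = ssm_em_iteration(
            ys, theta.A, theta.W, theta.structure.C, theta.V,
            theta.x1_bar, theta.W1_bar,
        )
        th = res.theta_hat
        np.testing.assert_allclose(th.x1_bar, x1_o, atol=1e-6)
        np.testing.assert_allclose(th.W1_bar, W1_o, atol=1e-6)
        np.testing.assert_allclose(th.A_bar, A_o, atol=1e-6)
        np.testing.assert_allclose(th.W_breve, W_o, atol=1e-6)
        np.testing.assert_allclose(th.V, V_o, atol=1e-6)

    def test_observed_loglik_monotone_with_alpha_frozen(self):
        """In the alpha=0 case EM is exact, so the observed-data log
        likelihood must be non-decreasing along the EM path."""
        patients = _simulated_ar1_patients(n=20, m=6, seed=8)
        s = build_canonical_structure(m_y=1, M=1, m_omega=1)
        theta = _ar1_model(A=0.5, W=0.5, V=0.5, x1=0.0, W1=2.0, gamma=(0.0,))
        lls = [gaussian_observed_loglik(patients, theta)]
        for _ in range(12):
            res = fit(
                patients, s, FitConfig(tol=1e12, max_iter=1, fix_alpha=True),
                theta0=theta,
            )
            theta = res.theta_hat
            lls.append(gaussian_observed_loglik(patients, theta))
        assert np.all(np.diff(lls) > -1e-8)

    def test_fit_deterministic_given_data(self, small_cohort):
        s = build_canonical_structure(m_y=1, M=2, m_omega=2)
        cfg = FitConfig(tol=1e-2, max_iter=30)
        r1 = fit(small_cohort.patients, s, cfg)
        r2 = fit(small_cohort.patients, s, cfg)
        assert r1.theta_hat.max_abs_diff(r2.theta_hat) == 0.0
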