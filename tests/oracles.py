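"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own inference code paths:
textbook Kalman recursions in gain form, dense joint-Gaussian
conditioning, and quadrature over the exact one-step posterior.
"""

import numpy as np


def kalman_predict(mu, Sigma, A, W):
    return A @ mu, A @ Sigma @ A.T + W


def kalman_update(mu, Sigma, y, C, V):
    """Textbook gain-form measurement update."""
    S = C @ Sigma @ C.T + V
    K = Sigma @ C.T @ np.linalg.inv(S)
    mu_post = mu + K @ (y - C @ mu)
    Sigma_post = (np.eye(mu.size) - K @ C) @ Sigma
    return mu_post, Sigma_post


def joint_gaussian_smoother(y_list, A, W, C, V, x1, W1):
    """Smoothed moments by dense conditioning on the stacked system.

    Builds the joint Gaussian of (x_1..x_m, y_1..y_m) explicitly and
    conditions on all observations; feasible for m <= 6 and small m_x.
    """
    m = len(y_list)
    m_x = x1.size
    m_y = y_list[0].size
    # joint covariance of stacked states
    mu_x = np.zeros(m * m_x)
    mu_x[:m_x] = x1
    P = np.zeros((m * m_x, m * m_x))
    P[:m_x, :m_x] = W1
    for j in range(1, m):
        mu_x[j * m_x : (j + 1) * m_x] = A @ mu_x[(j - 1) * m_x : j * m_x]
        for i in range(j):
            blk = P[i * m_x : (i + 1) * m_x, (j - 1) * m_x : j * m_x] @ A.T
            P[i * m_x : (i + 1) * m_x, j * m_x : (j + 1) * m_x] = blk
            P[j * m_x : (j + 1) * m_x, i * m_x : (i + 1) * m_x] = blk.T
        P[j * m_x : (j + 1) * m_x, j * m_x : (j + 1) * m_x] = (
            A @ P[(j - 1) * m_x : j * m_x, (j - 1) * m_x : j * m_x] @ A.T + W
        )
    Cbig = np.kron(np.eye(m), C)
    Vbig = np.kron(np.eye(m), V)
    y = np.concatenate(y_list)
    S = Cbig @ P @ Cbig.T + Vbig
    K = P @ Cbig.T @ np.linalg.inv(S)
    mu_post = mu_x + K @ (y - Cbig @ mu_x)
    P_post = P - K @ Cbig @ P
    means = [mu_post[j * m_x : (j + 1) * m_x] for j in range(m)]
    covs = [P_post[j * m_x : (j + 1) * m_x, j * m_x : (j + 1) * m_x] for j in range(m)]
    lag = [
        P_post[(j + 1) * m_x : (j + 2) * m_x, j * m_x : (j + 1) * m_x]
        for j in range(m - 1)
    ]
    return means, covs, lag


def posterior_1d_quadrature(mu_p, P, y=None, V=None, g=0.0, a=0.0,
                            tau=1.0, delta_bar=0.0, lo=-30, hi=30, n=200001):
    """Moments of the exact 1-D survival-corrected posterior.

    Integrand: N(y; x, V)^(y observed) * exp(db*(g+ax) - tau*exp(g+ax))
               * N(x; mu_p, P), normalized on a dense grid.  Returns
    (mean, variance, mode, curvature_variance): the last two are the
    density's argmax (golden-section refined) and the inverse negative
    second derivative of the log density there.
    """
    def logpdf(x):
        x = np.asarray(x, dtype=float)
        out = -0.5 * (x - mu_p) ** 2 / P
        if y is not None:
            out = out - 0.5 * (y - x) ** 2 / V
        eta = g + a * x
        return out + delta_bar * eta - tau * np.exp(np.clip(eta, -500, 500))

    xs = np.linspace(lo, hi, n)
    logw = logpdf(xs)
    logw -= logw.max()
    w = np.exp(logw)
    Z = np.trapezoid(w, xs)
    mean = np.trapezoid(w * xs, xs) / Z
    var = np.trapezoid(w * (xs - mean) ** 2, xs) / Z

    from scipy.optimize import minimize_scalar
    k = int(np.argmax(logw))
    res = minimize_scalar(
        lambda x: -logpdf(x), bracket=(xs[max(k - 1, 0)], xs[k], xs[min(k + 1, n - 1)]),
        method="brent", options={"xtol": 1e-12},
    )
    mode = float(res.x)
    h = 1e-5
    d2 = (logpdf(mode + h) - 2 * logpdf(mode) + logpdf(mode - h)) / h**2
    curv_var = -1.0 / d2
    return mean, var, mode, curv_var


def ssm_em_iteration(patients_y, A, W, C, V, x1, W1):
    """One EM iteration of a plain linear-Gaussian SSM (fully observed),
    via the dense joint-Gaussian smoother — a Shumway-Stoffer-style
    reference for the state-parameter updates with m_y = m_x.
    """
    n = len(patients_y)
    m_x = x1.size
    sum_mu1 = np.zeros(m_x)
    sum_E11 = np.zeros((m_x, m_x))
    S_lag = np.zeros((m_x, m_x))
    S_prev = np.zeros((m_x, m_x))
    S_curr = np.zeros((m_x, m_x))
    S_yy = np.zeros((m_x, m_x))
    S_yx = np.zeros((m_x, m_x))
    S_xx = np.zeros((m_x, m_x))
    n_trans = 0
    n_obs = 0
    for ys in patients_y:
        means, covs, lag = joint_gaussian_smoother(ys, A, W, C, V, x1, W1)
        E = [c + np.outer(mu, mu) for c, mu in zip(covs, means)]
        Elag = [l + np.outer(means[j + 1], means[j]) for j, l in enumerate(lag)]
        sum_mu1 += means[0]
        sum_E11 += E[0]
        for j in range(1, len(ys)):
            S_lag += Elag[j - 1]
            S_prev += E[j - 1]
            S_curr += E[j]
            n_trans += 1
        for j, y in enumerate(ys):
            S_yy += np.outer(y, y)
            S_yx += np.outer(y, means[j])
            S_xx += E[j]
            n_obs += 1
    x1_new = sum_mu1 / n
    W1_new = sum_E11 / n - np.outer(x1_new, x1_new)
    A_new = S_lag @ np.linalg.inv(S_prev)
    W_new = (S_curr - S_lag @ A_new.T - A_new @ S_lag.T + A_new @ S_prev @ A_new.T) / n_trans
    V_new = (S_yy - S_yx @ C.T - C @ S_yx.T + C @ S_xx @ C.T) / n_obs
    return x1_new, W1_new, A_new, W_new, V_new
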