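"""Dense brute-force reference path for the Laplace likelihood.

Builds the full joint prior covariance over (field, year effect, nugget)
elementwise — no Kronecker factorisation, no nugget elimination — and runs a
plain dense Newton iteration on the complete latent vector.  Exists purely as
an independent check of the structured implementation on small problems.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla

from .model import LGCPModel

_LOG2PI = np.log(2.0 * np.pi)


def laplace_nll_dense(model: LGCPModel, params, tol: float = 1e-10,
                      maxiter: int = 200) -> float:
    """Laplace marginal negative log-likelihood via the dense full-latent path."""
    cfg = model.config
    theta = model.pack(params)
    params = model.unpack(theta)       # normalise through the same mapping
    gamma = theta[model.n_var:]
    eta_fix = model.X @ gamma

    C, Y, n = model.C, model.Y, model.n
    blocks = []
    if cfg.include_field:
        dist = model.dist_km
        lag = np.abs(np.subtract.outer(np.arange(Y), np.arange(Y)))
        spatial_corr = np.exp(-params.alpha * dist) + cfg.jitter * np.eye(C)
        temporal_corr = np.exp(-params.beta * lag) + cfg.jitter * np.eye(Y)
        m1 = C * Y
        cov_f = np.empty((m1, m1))
        for c1 in range(C):
            for c2 in range(C):
                cov_f[c1 * Y:(c1 + 1) * Y, c2 * Y:(c2 + 1) * Y] = (
                    params.sigma_sq * spatial_corr[c1, c2] * temporal_corr)
        blocks.append(cov_f)
    if cfg.include_year_effect:
        lag = np.abs(np.subtract.outer(np.arange(Y), np.arange(Y)))
        cov_y = params.sigma_y_sq * (np.exp(-params.beta * lag) + cfg.jitter * np.eye(Y))
        blocks.append(cov_y)
    if cfg.include_nugget:
        blocks.append(params.sigma0_sq * np.eye(n))
    if not blocks:
        f, _, _ = model._obs_terms(eta_fix)
        return f

    Sigma = sla.block_diag(*blocks)
    m = Sigma.shape[0]
    Q = np.linalg.inv(Sigma)
    sign, logdet_Sigma = np.linalg.slogdet(Sigma)

    # full incidence matrix: field col, year col, own nugget col
    A = np.zeros((n, m))
    off = 0
    if cfg.include_field:
        A[np.arange(n), model.kf] = 1.0
        off += C * Y
    if cfg.include_year_effect:
        A[np.arange(n), off + model.yi] = 1.0
        off += Y
    if cfg.include_nugget:
        A[np.arange(n), off + np.arange(n)] = 1.0

    u = np.zeros(m)

    def joint(u):
        eta = eta_fix + A @ u
        f_obs, g, w = model._obs_terms(eta)
        f = f_obs + 0.5 * u @ (Q @ u) + 0.5 * (m * _LOG2PI + logdet_Sigma)
        return f, g, w, eta

    f, g, w, eta = joint(u)
    for _ in range(maxiter):
        grad = Q @ u + A.T @ g
        if np.abs(grad).max() < tol:
            break
        H = Q + A.T @ (w[:, None] * A)
        du = -np.linalg.solve(H, grad)
        step = 1.0
        while step > 1e-12:
            f_new, g_new, w_new, eta_new = joint(u + step * du)
            if np.isfinite(f_new) and f_new <= f + 1e-12 * abs(f):
                break
            step *= 0.5
        u, f, g, w, eta = u + step * du, f_new, g_new, w_new, eta_new

    H = Q + A.T @ (w[:, None] * A)
    sign_h, logdetH = np.linalg.slogdet(H)
    return f + 0.5 * logdetH - 0.5 * m * _LOG2PI
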