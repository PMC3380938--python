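"""Log-Gaussian Cox model for survey count data, fitted by Laplace-approximated ML.

:class:`LGCPModel` is constructed from a validated sample table and a
:class:`~lgcpindex.grid.GridSpec`; :meth:`LGCPModel.fit` maximises the
Laplace-approximated marginal likelihood over the structural parameters and
returns an :class:`~lgcpindex.results.LGCPResults`.

The latent vector u = (field, year effect, nugget) enters the Poisson
log-intensity through a sparse incidence structure: each sample touches one
field value (its cell-year), one year effect and its own nugget.  The inner
(latent) problem is strictly convex and solved by Newton iteration with step
halving; the nugget block is eliminated analytically, so each step factorises
only the (cells x years + years) reduced Hessian.  The outer gradient is exact
(implicit differentiation through the latent mode), which keeps quasi-Newton
outer optimisation cheap enough for simulation studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2

from .covariance import CovarianceStructure
from .grid import GridSpec
from .params import ModelParams

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LatentState:
    """Values of the latent Gaussian components.

    ``field`` is (n_cells, n_years); ``year_effect`` is (n_years,); ``nugget``
    is per-sample (or None when the nugget is disabled).
    """
    field: np.ndarray
    year_effect: np.ndarray
    nugget: np.ndarray | None = None


@dataclass
class LGCPConfig:
    """Which effects are active, covariate conditioning, and tolerances."""

    include_field: bool = True
    include_year_effect: bool = True
    include_nugget: bool = True
    thermocline_effect: bool = True
    hour_effect: bool = False
    period_cut: tuple[int, int] | None = None   # (cut_before, cut_after): offset for year > cut_after
    tie_sigma_y: bool = False                   # sigma_y^2 == sigma^2
    family: str = "poisson"                     # "gaussian" is a validation gauge (Laplace exact)
    obs_sigma: float = 1.0                      # observation s.d. for the gaussian family
    day_center: float = 183.0
    day_scale: float = 100.0
    thc_center: float = 30.0
    thc_scale: float = 10.0
    missing_thc_policy: str = "deep"            # "deep" | "error"
    missing_thc_depth: float = 60.0
    jitter: float = 1e-8
    inner_tol: float = 1e-8
    inner_maxiter: int = 100
    outer_tol: float = 1e-6
    outer_maxiter: int = 300


class InnerConvergenceError(RuntimeError):
    pass


class _NonFiniteObjective(RuntimeError):
    """Trial parameter point where the joint density is non-finite everywhere."""


# hour-of-day offsets: 23 free contrasts, offsets sum to zero
_HOUR_CONTRAST = np.vstack([np.eye(23), -np.ones((1, 23))])


class LGCPModel:
    """Log-Gaussian Cox process model bound to one sample table.

    Parameters
    ----------
    samples : DataFrame with the sample-table schema (``cell_id`` is assigned
        from ``grid`` if absent).
    grid : GridSpec defining the latent field's cells.
    years : (first, last) calendar years of the latent field, inclusive;
        defaults to the data range.
    config : LGCPConfig.
    """

    def __init__(self, samples: pd.DataFrame, grid: GridSpec,
                 years: tuple[int, int] | None = None,
                 config: LGCPConfig | None = None):
        from .data import assign_cells

        self.config = config or LGCPConfig()
        self.grid = grid
        if "cell_id" not in samples.columns:
            samples = assign_cells(samples, grid)
        self.samples = samples.reset_index(drop=True)
        cfg = self.config

        if years is None:
            if len(samples) == 0:
                raise ValueError("years must be given for an empty sample table")
            years = (int(samples["year"].min()), int(samples["year"].max()))
        self.year0, self.year1 = int(years[0]), int(years[1])
        self.years = np.arange(self.year0, self.year1 + 1)
        self.Y = len(self.years)
        self.C = grid.n_cells
        self.n = len(self.samples)

        # latent layout: [field (C*Y, cell-major) | year effect (Y)] + nugget
        self.m1 = self.C * self.Y if cfg.include_field else 0
        self.mU = self.Y if cfg.include_year_effect else 0
        self.mz = self.m1 + self.mU
        self.has_eps = cfg.include_nugget

        yi = self.samples["year"].to_numpy() - self.year0
        if (yi < 0).any() or (yi >= self.Y).any():
            raise ValueError("sample years outside the model year range")
        self.yi = yi
        cell = self.samples["cell_id"].to_numpy()
        self.kf = cell * self.Y + yi if cfg.include_field else None
        self.ku = self.m1 + yi if cfg.include_year_effect else None

        rows, cols = [], []
        if self.kf is not None:
            rows.append(np.arange(self.n)); cols.append(self.kf)
        if self.ku is not None:
            rows.append(np.arange(self.n)); cols.append(self.ku)
        if self.mz and self.n:
            self.B = sp.csr_matrix((np.ones(sum(len(r) for r in rows)),
                                    (np.concatenate(rows), np.concatenate(cols))),
                                   shape=(self.n, self.mz))
        else:
            self.B = sp.csr_matrix((self.n, self.mz))

        self.N = self.samples["count"].to_numpy(dtype=float) if self.n else np.zeros(0)
        self.dist_km = grid.distance_matrix_km()
        self._build_design()

    # ------------------------------------------------------------------ design

    def _build_design(self):
        cfg = self.config
        names: list[str] = ["const"]
        cols: list[np.ndarray] = [np.ones(self.n)]

        d = self.samples["day_of_year"].to_numpy(dtype=float) if self.n else np.zeros(0)
        ds = (d - cfg.day_center) / cfg.day_scale
        names += ["day_c", "day_c2"]
        cols += [ds, ds ** 2]

        if cfg.thermocline_effect:
            t = (self.samples["thermocline_depth_m"].to_numpy(dtype=float)
                 if self.n else np.zeros(0))
            if np.isnan(t).any():
                if cfg.missing_thc_policy == "error":
                    raise ValueError("missing thermocline depths and policy is 'error'")
                t = np.where(np.isnan(t), cfg.missing_thc_depth, t)
            ts = (t - cfg.thc_center) / cfg.thc_scale
            names += ["thc_c", "thc_c2"]
            cols += [ts, ts ** 2]

        if cfg.period_cut is not None:
            _, cut_after = cfg.period_cut
            late = (self.samples["year"].to_numpy() > cut_after).astype(float) \
                if self.n else np.zeros(0)
            names += ["period_shift"]
            cols += [late]

        if cfg.hour_effect:
            h = self.samples["hour"].to_numpy() if self.n else np.zeros(0, dtype=int)
            onehot = np.zeros((self.n, 24))
            if self.n:
                onehot[np.arange(self.n), h] = 1.0
            H = onehot @ _HOUR_CONTRAST
            names += [f"hour_{j}" for j in range(23)]
            cols += [H[:, j] for j in range(23)]

        self.X = np.column_stack(cols) if self.n else np.zeros((0, len(names)))
        self.fixed_names = names

        self.theta_names: list[str] = []
        if self.has_eps:
            self.theta_names.append("log_sigma0_sq")
        if cfg.include_field:
            self.theta_names += ["log_sigma_sq", "log_alpha", "log_beta"]
        if cfg.include_year_effect and not cfg.tie_sigma_y:
            self.theta_names.append("log_sigma_y_sq")
        if cfg.include_year_effect and not cfg.include_field:
            if "log_beta" not in self.theta_names:
                self.theta_names.append("log_beta")
            if cfg.tie_sigma_y:
                raise ValueError("tie_sigma_y requires the field component")
        self.theta_names += self.fixed_names
        self.n_var = len(self.theta_names) - len(self.fixed_names)

    # ------------------------------------------------- parameter vector mapping

    def pack(self, params: ModelParams) -> np.ndarray:
        """Internal optimiser vector from raw-scale ModelParams."""
        cfg = self.config
        v: dict[str, float] = {}
        if self.has_eps:
            v["log_sigma0_sq"] = np.log(params.sigma0_sq)
        if cfg.include_field:
            v["log_sigma_sq"] = np.log(params.sigma_sq)
            v["log_alpha"] = params.log_alpha
            v["log_beta"] = params.log_beta
        if cfg.include_year_effect and not cfg.tie_sigma_y:
            v["log_sigma_y_sq"] = np.log(params.sigma_y_sq)
        if cfg.include_year_effect and not cfg.include_field:
            v["log_beta"] = params.log_beta

        sd, d0 = cfg.day_scale, cfg.day_center
        g2 = -params.a_spawn2 * sd ** 2
        g1 = sd * (params.a_spawn1 - 2.0 * params.a_spawn2 * d0)
        const = params.intercept + g1 * d0 / sd - g2 * d0 ** 2 / sd ** 2
        v["day_c"], v["day_c2"] = g1, g2
        if cfg.thermocline_effect:
            st, t0 = cfg.thc_scale, cfg.thc_center
            g4 = -params.a_thc2 * st ** 2
            g3 = st * (params.a_thc1 - 2.0 * params.a_thc2 * t0)
            const += g3 * t0 / st - g4 * t0 ** 2 / st ** 2
            v["thc_c"], v["thc_c2"] = g3, g4
        v["const"] = const
        if cfg.period_cut is not None:
            v["period_shift"] = params.period_shift or 0.0
        if cfg.hour_effect:
            mu = params.mu_hour if params.mu_hour is not None else np.zeros(24)
            mu = mu - mu.mean()
            for j in range(23):
                v[f"hour_{j}"] = mu[j]
        return np.array([v[nm] for nm in self.theta_names])

    def unpack(self, theta: np.ndarray) -> ModelParams:
        """Raw-scale ModelParams from the internal optimiser vector."""
        cfg = self.config
        v = dict(zip(self.theta_names, theta))
        sd, d0 = cfg.day_scale, cfg.day_center
        g1, g2 = v["day_c"], v["day_c2"]
        a2 = -g2 / sd ** 2
        a1 = g1 / sd - 2.0 * g2 * d0 / sd ** 2
        intercept = v["const"] - g1 * d0 / sd + g2 * d0 ** 2 / sd ** 2
        if cfg.thermocline_effect:
            st, t0 = cfg.thc_scale, cfg.thc_center
            g3, g4 = v["thc_c"], v["thc_c2"]
            b2 = -g4 / st ** 2
            b1 = g3 / st - 2.0 * g4 * t0 / st ** 2
            intercept += -g3 * t0 / st + g4 * t0 ** 2 / st ** 2
        else:
            b1, b2 = 0.0, 0.0
        mu_hour = None
        if cfg.hour_effect:
            psi = np.array([v[f"hour_{j}"] for j in range(23)])
            mu_hour = _HOUR_CONTRAST @ psi
        sigma_sq = np.exp(v["log_sigma_sq"]) if cfg.include_field else 0.0
        if cfg.include_year_effect:
            sigma_y_sq = sigma_sq if cfg.tie_sigma_y else np.exp(v["log_sigma_y_sq"])
        else:
            sigma_y_sq = 0.0
        return ModelParams(
            sigma0_sq=np.exp(v["log_sigma0_sq"]) if self.has_eps else 0.0,
            sigma_sq=sigma_sq, sigma_y_sq=sigma_y_sq,
            log_alpha=v.get("log_alpha", 0.0), log_beta=v.get("log_beta", 0.0),
            intercept=intercept, a_spawn1=a1, a_spawn2=a2, a_thc1=b1, a_thc2=b2,
            mu_hour=mu_hour,
            period_shift=v.get("period_shift"),
        )

    def raw_param_table(self, theta: np.ndarray, cov_theta: np.ndarray | None):
        """Raw-scale parameter names, values and (delta-method) standard errors."""
        cfg = self.config
        p = len(theta)
        idx = {nm: j for j, nm in enumerate(self.theta_names)}
        rows: list[tuple[str, float, np.ndarray]] = []

        def jac_row(**deriv):
            r = np.zeros(p)
            for nm, val in deriv.items():
                r[idx[nm]] = val
            return r

        params = self.unpack(theta)
        if self.has_eps:
            rows.append(("sigma0_sq", params.sigma0_sq,
                         jac_row(log_sigma0_sq=params.sigma0_sq)))
        if cfg.include_field:
            rows.append(("sigma_sq", params.sigma_sq, jac_row(log_sigma_sq=params.sigma_sq)))
            rows.append(("log_alpha", params.log_alpha, jac_row(log_alpha=1.0)))
        if cfg.include_year_effect and not cfg.tie_sigma_y:
            rows.append(("sigma_y_sq", params.sigma_y_sq,
                         jac_row(log_sigma_y_sq=params.sigma_y_sq)))
        if "log_beta" in idx:
            rows.append(("log_beta", params.log_beta, jac_row(log_beta=1.0)))

        sd, d0 = cfg.day_scale, cfg.day_center
        rows.append(("a_spawn1", params.a_spawn1,
                     jac_row(day_c=1.0 / sd, day_c2=-2.0 * d0 / sd ** 2)))
        rows.append(("a_spawn2", params.a_spawn2, jac_row(day_c2=-1.0 / sd ** 2)))
        ic = {"const": 1.0, "day_c": -d0 / sd, "day_c2": d0 ** 2 / sd ** 2}
        if cfg.thermocline_effect:
            st, t0 = cfg.thc_scale, cfg.thc_center
            rows.append(("a_thc1", params.a_thc1,
                         jac_row(thc_c=1.0 / st, thc_c2=-2.0 * t0 / st ** 2)))
            rows.append(("a_thc2", params.a_thc2, jac_row(thc_c2=-1.0 / st ** 2)))
            ic.update({"thc_c": -t0 / st, "thc_c2": t0 ** 2 / st ** 2})
        rows.append(("intercept", params.intercept, jac_row(**ic)))
        if cfg.period_cut is not None:
            rows.append(("period_shift", params.period_shift or 0.0,
                         jac_row(period_shift=1.0)))

        names = [r[0] for r in rows]
        values = np.array([r[1] for r in rows])
        J = np.vstack([r[2] for r in rows])
        if cov_theta is None:
            se = np.full(len(rows), np.nan)
        else:
            se = np.sqrt(np.clip(np.diag(J @ cov_theta @ J.T), 0.0, None))
        return names, values, se

    # ----------------------------------------------------------- observations

    def _obs_terms(self, eta: np.ndarray):
        """(nll, gradient, curvature) of the observation term at eta.

        Gradient/curvature are of the *negative* log-likelihood w.r.t. eta.
        """
        if self.config.family == "poisson":
            with np.errstate(over="ignore"):
                f = float(np.sum(np.exp(eta) - self.N * eta)
                          + np.sum(gammaln(self.N + 1.0)))
            # curvature weights are clipped so Newton algebra stays finite even
            # when a trial point overflows; f keeps the true (possibly inf) value
            w = np.exp(np.minimum(eta, 100.0))
            return f, w - self.N, w
        tau2 = self.config.obs_sigma ** 2
        resid = eta - self.N        # gaussian gauge: counts column holds real obs
        f = float(0.5 * np.sum(resid ** 2) / tau2 + 0.5 * self.n * np.log(2 * np.pi * tau2))
        return f, resid / tau2, np.full(self.n, 1.0 / tau2)

    # ------------------------------------------------------- parameter context

    def _context(self, theta: np.ndarray):
        params = self.unpack(theta)
        cfg = self.config
        ctx = {"params": params, "theta": theta}
        gamma = theta[self.n_var:]
        ctx["gamma"] = gamma
        ctx["eta_fixed"] = self.X @ gamma if self.n else np.zeros(0)

        need_cov = cfg.include_field or cfg.include_year_effect
        cov = CovarianceStructure(params, self.dist_km, self.Y, cfg.jitter) if need_cov else None
        ctx["cov"] = cov

        Qz = np.zeros((self.mz, self.mz))
        logdet_prior = 0.0
        if cfg.include_field:
            s2i = 1.0 / params.sigma_sq
            Qz[:self.m1, :self.m1] = s2i * np.kron(cov.Rs_inv, cov.Rt_inv)
            logdet_prior += cov.logdet_field_cov()
        if cfg.include_year_effect:
            Qz[self.m1:, self.m1:] = cov.Rt_inv / params.sigma_y_sq
            logdet_prior += cov.logdet_year_cov()
        if self.has_eps:
            logdet_prior += self.n * np.log(params.sigma0_sq)
        ctx["Qz"] = Qz
        ctx["logdet_prior"] = logdet_prior
        ctx["m_latent"] = self.mz + (self.n if self.has_eps else 0)
        return ctx

    def _joint_f(self, ctx, z, eps):
        """Joint negative log density of (data, latents), full normalisation."""
        eta = ctx["eta_fixed"] + (self.B @ z if self.mz else 0.0) \
            + (eps if self.has_eps else 0.0)
        f_obs, _, _ = self._obs_terms(eta)
        f = f_obs + 0.5 * ctx["m_latent"] * _LOG2PI + 0.5 * ctx["logdet_prior"]
        if self.mz:
            f += 0.5 * float(z @ (ctx["Qz"] @ z))
        if self.has_eps:
            f += 0.5 * float(eps @ eps) / ctx["params"].sigma0_sq
        return f, eta

    # ---------------------------------------------------------- inner problem

    def _inner_mode(self, ctx, warm=None):
        """Newton iteration (step halving) for the latent joint mode.

        Returns a dict with the mode, curvatures and the factorised reduced
        Hessian; the nugget block is eliminated analytically.
        """
        cfg = self.config
        s0 = ctx["params"].sigma0_sq if self.has_eps else None
        z = np.zeros(self.mz) if warm is None else warm[0].copy()
        eps = (np.zeros(self.n) if (warm is None or warm[1] is None) else warm[1].copy()) \
            if self.has_eps else None

        f, eta = self._joint_f(ctx, z, eps)
        if warm is not None:
            # a warm start from a distant parameter point can be worse than the
            # latent origin; take whichever is better
            z0 = np.zeros(self.mz)
            e0 = np.zeros(self.n) if self.has_eps else None
            f0, eta0 = self._joint_f(ctx, z0, e0)
            if not np.isfinite(f) or f0 < f:
                z, eps, f, eta = z0, e0, f0, eta0
        if not np.isfinite(f):
            raise _NonFiniteObjective
        trace = []
        converged = self.mz == 0 and not self.has_eps
        stall = 0
        for it in range(cfg.inner_maxiter):
            if converged:
                break
            _, g, w = self._obs_terms(eta)
            grad_z = ctx["Qz"] @ z + self.B.T @ g if self.mz else np.zeros(0)
            grad_e = eps / s0 + g if self.has_eps else np.zeros(0)
            gmax = max(np.abs(grad_z).max() if self.mz else 0.0,
                       np.abs(grad_e).max() if (self.has_eps and self.n) else 0.0)
            trace.append((it, f, gmax))
            # relative floor keeps the criterion attainable at double precision
            if gmax < max(cfg.inner_tol, 1e-9 * abs(f)):
                converged = True
                break

            if self.has_eps:
                D = w + 1.0 / s0
                wt = w / (1.0 + s0 * w)
            else:
                D = None
                wt = w
            if self.mz:
                S = ctx["Qz"] + (self.B.T.multiply(wt) @ self.B).toarray()
                cho_S = sla.cho_factor(S, lower=True)
                rhs = grad_z - (self.B.T @ (w * grad_e / D) if self.has_eps else 0.0)
                dz = -sla.cho_solve(cho_S, rhs)
            else:
                dz = np.zeros(0)
            de = -(grad_e + w * (self.B @ dz if self.mz else 0.0)) / D \
                if self.has_eps else None

            step = 1.0
            accepted = False
            for _ in range(40):
                z_new = z + step * dz
                e_new = eps + step * de if self.has_eps else None
                f_new, eta_new = self._joint_f(ctx, z_new, e_new)
                if np.isfinite(f_new) and f_new <= f + 1e-12 * abs(f):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                # clipped-curvature direction failed to descend: reject the
                # trial parameter point rather than report a bogus mode
                if gmax < 1e-4 * max(1.0, abs(f)):
                    converged = True     # numerically at the mode already
                    break
                raise _NonFiniteObjective
            # stagnation at double precision: the gradient has hit its floor
            if abs(f - f_new) <= 1e-12 * max(1.0, abs(f)):
                stall += 1
                if stall >= 3:
                    z, eps, f, eta = z_new, e_new, f_new, eta_new
                    converged = True
                    break
            else:
                stall = 0
            z, eps, f, eta = z_new, e_new, f_new, eta_new
        else:
            if not converged:
                raise InnerConvergenceError(
                    f"inner Newton did not converge in {cfg.inner_maxiter} iterations; "
                    f"trace (iter, f, |grad|): {trace[-5:]}")

        # curvatures and factorisation at the mode
        _, g, w = self._obs_terms(eta)
        if self.has_eps:
            D = w + 1.0 / s0
            wt = w / (1.0 + s0 * w)
        else:
            D = None
            wt = w
        logdetH = float(np.sum(np.log(D))) if self.has_eps else 0.0
        cho_S = None
        if self.mz:
            S = ctx["Qz"] + (self.B.T.multiply(wt) @ self.B).toarray()
            cho_S = sla.cho_factor(S, lower=True)
            logdetH += 2.0 * float(np.sum(np.log(np.diag(cho_S[0]))))
        return {"z": z, "eps": eps, "eta": eta, "f": f, "g": g, "w": w,
                "D": D, "wt": wt, "cho_S": cho_S, "logdetH": logdetH}

    # --------------------------------------------------------------- laplace

    def laplace_nll(self, params_or_theta, warm=None, return_mode=False):
        """Negative Laplace-approximated marginal log-likelihood.

        Accepts a :class:`ModelParams` or an internal parameter vector.
        """
        theta = (params_or_theta if isinstance(params_or_theta, np.ndarray)
                 else self.pack(params_or_theta))
        ctx = self._context(theta)
        mode = self._inner_mode(ctx, warm)
        nll = mode["f"] + 0.5 * mode["logdetH"] - 0.5 * ctx["m_latent"] * _LOG2PI
        if return_mode:
            return nll, mode
        return nll

    def joint_nll(self, params: ModelParams, latent: LatentState, parts=False):
        """Joint negative log density at explicit latent values.

        With ``parts=True`` returns a dict with the observation and prior
        contributions separately.
        """
        theta = self.pack(params)
        ctx = self._context(theta)
        z = np.concatenate([
            latent.field.ravel() if self.config.include_field else np.zeros(0),
            latent.year_effect if self.config.include_year_effect else np.zeros(0)])
        eps = latent.nugget if self.has_eps else None
        f, eta = self._joint_f(ctx, z, eps)
        if not parts:
            return f
        f_obs, _, _ = self._obs_terms(eta)
        return {"total": f, "obs": f_obs, "prior": f - f_obs, "eta": eta}

    def _laplace_grad(self, theta: np.ndarray, warm=None):
        """(nll, analytic gradient, mode) at theta."""
        cfg = self.config
        ctx = self._context(theta)
        mode = self._inner_mode(ctx, warm)
        params = ctx["params"]
        nll = mode["f"] + 0.5 * mode["logdetH"] - 0.5 * ctx["m_latent"] * _LOG2PI

        z, eps, g, w = mode["z"], mode["eps"], mode["g"], mode["w"]
        D, cho_S = mode["D"], mode["cho_S"]
        cov = ctx["cov"]

        S_inv = None
        if self.mz:
            S_inv, info = sla.lapack.dpotri(cho_S[0], lower=True)
            if info != 0:
                raise np.linalg.LinAlgError("dpotri failed on the reduced Hessian")
            S_inv = np.tril(S_inv) + np.tril(S_inv, -1).T   # dpotri fills one triangle

        # q_i = b_i' S^{-1} b_i for each sample's incidence row
        if self.mz and self.n:
            q = np.zeros(self.n)
            if self.kf is not None:
                q += S_inv[self.kf, self.kf]
            if self.ku is not None:
                q += S_inv[self.ku, self.ku]
            if self.kf is not None and self.ku is not None:
                q += 2.0 * S_inv[self.kf, self.ku]
        else:
            q = np.zeros(self.n)

        if self.has_eps:
            shrink = 1.0 / (1.0 + params.sigma0_sq * w)   # = (1/s0)/D
            s_diag = shrink ** 2 * q + 1.0 / D
            P_ee = 1.0 / D + (w / D) ** 2 * q
        else:
            s_diag = q
            P_ee = None

        # implicit-term solve: r = H^{-1} c with c = 0.5 * A'(s*w)
        if cfg.family == "poisson":
            sw = s_diag * w
            c_z = 0.5 * (self.B.T @ sw) if self.mz else np.zeros(0)
            if self.has_eps:
                c_e = 0.5 * sw
                rhs = c_z - (self.B.T @ (w * c_e / D) if self.mz else 0.0)
                r_z = sla.cho_solve(cho_S, rhs) if self.mz else np.zeros(0)
                r_e = (c_e - w * (self.B @ r_z if self.mz else 0.0)) / D
            else:
                r_z = sla.cho_solve(cho_S, c_z) if self.mz else np.zeros(0)
                r_e = None
            t = (self.B @ r_z if self.mz else 0.0) + (r_e if self.has_eps else 0.0)
        else:   # gaussian: curvature independent of eta, implicit terms vanish
            sw = np.zeros(self.n)
            r_z, r_e, t = np.zeros(self.mz), np.zeros(self.n), np.zeros(self.n)

        grad = np.zeros(len(theta))
        # fixed effects
        gfix = self.X.T @ (g + 0.5 * sw - w * t) if self.n else np.zeros(self.X.shape[1])
        grad[self.n_var:] = gfix

        def block_grad(dQ, sl, dlogdet):
            zb = z[sl]
            val = 0.5 * float(zb @ (dQ @ zb)) + 0.5 * dlogdet
            val += 0.5 * float(np.sum(S_inv[sl, sl] * dQ))
            val -= float(r_z[sl] @ (dQ @ zb))
            return val

        iname = {nm: j for j, nm in enumerate(self.theta_names)}
        slF = slice(0, self.m1)
        slU = slice(self.m1, self.mz)

        if self.has_eps:
            s0 = params.sigma0_sq
            val = (-0.5 * float(eps @ eps) / s0 + 0.5 * self.n
                   - 0.5 * float(np.sum(P_ee)) / s0
                   + float(r_e @ eps) / s0)
            grad[iname["log_sigma0_sq"]] = val

        if cfg.include_field:
            QF = ctx["Qz"][slF, slF]
            gv = block_grad(-QF, slF, self.m1)
            if cfg.tie_sigma_y:
                QU = ctx["Qz"][slU, slU]
                gv += block_grad(-QU, slU, self.Y)
            grad[iname["log_sigma_sq"]] = gv

            dRs = cov.dRs_dlogalpha()
            dRs_inv = -cov.Rs_inv @ dRs @ cov.Rs_inv
            dQF = np.kron(dRs_inv, cov.Rt_inv) / params.sigma_sq
            grad[iname["log_alpha"]] = block_grad(
                dQF, slF, self.Y * float(np.trace(cov.Rs_inv @ dRs)))

        if cfg.include_year_effect and not cfg.tie_sigma_y:
            QU = ctx["Qz"][slU, slU]
            grad[iname["log_sigma_y_sq"]] = block_grad(-QU, slU, self.Y)

        if "log_beta" in iname:
            dRt = cov.dRt_dlogbeta()
            dRt_inv = -cov.Rt_inv @ dRt @ cov.Rt_inv
            tr_t = float(np.trace(cov.Rt_inv @ dRt))
            gv = 0.0
            if cfg.include_field:
                dQF = np.kron(cov.Rs_inv, dRt_inv) / params.sigma_sq
                gv += block_grad(dQF, slF, self.C * tr_t)
            if cfg.include_year_effect:
                dQU = dRt_inv / params.sigma_y_sq
                gv += block_grad(dQU, slU, tr_t)
            grad[iname["log_beta"]] = gv

        return nll, grad, mode

    # -------------------------------------------------------------------- fit

    def fit(self, start: ModelParams | None = None, compute_se: bool = True,
            maxiter: int | None = None, verbose: bool = False):
        """Maximise the Laplace marginal likelihood; return LGCPResults.

        Variances and decay rates are optimised on the log scale; standard
        errors come from a finite-difference Hessian of the analytic outer
        gradient, back-transformed to the raw parameter scale.
        """
        from .results import LGCPResults

        cfg = self.config
        theta0 = self.pack(start if start is not None else self._default_start())
        if start is None and self.n and cfg.family == "poisson":
            theta0[self.n_var:] = self._irls_gamma(theta0[self.n_var:])
        state: dict = {"warm": None}

        def objective(theta):
            try:
                nll, grad, mode = self._laplace_grad(theta, warm=state["warm"])
            except _NonFiniteObjective:
                return np.inf, np.zeros_like(theta)
            state["warm"] = (mode["z"], mode["eps"])
            if verbose:
                print(f"  nll={nll:.4f}  |g|={np.abs(grad).max():.2e}")
            return nll, grad

        bounds = []
        for nm in self.theta_names:
            if nm.startswith("log_sigma"):
                bounds.append((-12.0, 6.0))
            elif nm == "log_alpha":
                bounds.append((-12.0, 2.0))
            elif nm == "log_beta":
                bounds.append((-8.0, 3.0))
            else:
                bounds.append((None, None))

        res = minimize(objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter or cfg.outer_maxiter,
                                "ftol": 1e-10, "gtol": cfg.outer_tol})
        theta_hat = res.x
        nll, grad, mode = self._laplace_grad(theta_hat, warm=state["warm"])

        cov_theta = None
        if compute_se:
            at_bound = np.array([
                (lo is not None and abs(th - lo) < 1e-6)
                or (hi is not None and abs(th - hi) < 1e-6)
                for th, (lo, hi) in zip(theta_hat, bounds)])
            cov_theta = self._outer_cov(theta_hat, warm=(mode["z"], mode["eps"]),
                                        fixed=at_bound)
        return LGCPResults(self, theta_hat, nll, grad, mode, cov_theta,
                           converged=bool(res.success), optimizer_result=res)

    def _irls_gamma(self, gamma0: np.ndarray, n_iter: int = 12) -> np.ndarray:
        """Poisson-regression starting values for the fixed effects (IRLS)."""
        gamma = gamma0.copy()
        X, N = self.X, self.N
        for _ in range(n_iter):
            eta = np.clip(X @ gamma, -30.0, 20.0)
            w = np.exp(eta)
            H = X.T @ (w[:, None] * X) + 1e-6 * np.eye(X.shape[1])
            g = X.T @ (w - N)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            gamma = gamma - np.clip(step, -5.0, 5.0)
        return gamma

    def results_at(self, params_or_theta, compute_se: bool = False):
        """Results object evaluated at a given parameter point (no optimisation)."""
        from .results import LGCPResults

        theta = (params_or_theta if isinstance(params_or_theta, np.ndarray)
                 else self.pack(params_or_theta))
        nll, grad, mode = self._laplace_grad(theta)
        cov_theta = self._outer_cov(theta, warm=(mode["z"], mode["eps"])) \
            if compute_se else None
        return LGCPResults(self, theta, nll, grad, mode, cov_theta, converged=True)

    def _default_start(self) -> ModelParams:
        """Moment-flavoured neutral starting point."""
        mean_ct = float(self.N.mean()) if self.n else 1.0
        return ModelParams(
            sigma0_sq=1.0, sigma_sq=1.0, sigma_y_sq=0.5,
            log_alpha=-5.0, log_beta=-1.0,
            intercept=np.log(max(mean_ct, 0.05)),
            a_spawn1=0.0, a_spawn2=1e-5, a_thc1=0.0, a_thc2=1e-4,
            mu_hour=np.zeros(24) if self.config.hour_effect else None,
            period_shift=0.0 if self.config.period_cut is not None else None)

    def _outer_cov(self, theta: np.ndarray, warm=None, rel_step: float = 1e-4,
                   fixed: np.ndarray | None = None):
        """Covariance of theta from a central-difference Hessian of the gradient.

        Parameters at an active bound (``fixed`` mask) are held out of the
        inversion: the likelihood is flat or one-sided there, and including
        them would corrupt every standard error.  Their variance is reported
        as 0 (the estimate sits on the boundary).
        """
        p = len(theta)
        free = np.flatnonzero(~fixed) if fixed is not None else np.arange(p)
        _, g0, _ = self._laplace_grad(theta, warm=warm)
        H = np.zeros((p, p))
        for j in free:
            h = rel_step * max(1.0, abs(theta[j]))
            tp = theta.copy(); tp[j] += h
            _, gp, _ = self._laplace_grad(tp, warm=warm)
            H[j] = (gp - g0) / h
        Hf = 0.5 * (H[np.ix_(free, free)] + H[np.ix_(free, free)].T)
        try:
            cov_f = np.linalg.inv(Hf)
        except np.linalg.LinAlgError:
            cov_f = np.linalg.pinv(Hf)
        if (np.diag(cov_f) < 0).any():
            warnings.warn("outer Hessian not positive definite; SEs use pseudo-inverse "
                          "and may be unreliable", stacklevel=2)
            cov_f = np.linalg.pinv(Hf)
        cov = np.zeros((p, p))
        cov[np.ix_(free, free)] = cov_f
        return cov


def lr_test(fit_full, fit_reduced, df: int):
    """Likelihood-ratio test of nested Laplace fits.

    statistic = 2 * (nll_reduced - nll_full); p-value from chi^2(df).
    A materially negative statistic indicates optimiser failure and raises.
    """
    stat = 2.0 * (fit_reduced.nll - fit_full.nll)
    tol = 1e-4 * max(1.0, abs(fit_full.nll))
    if stat < -tol:
        raise RuntimeError(
            f"negative LR statistic ({stat:.4g}): the full model fit is worse than "
            "the reduced one; check optimiser convergence")
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df))
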