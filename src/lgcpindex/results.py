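"""Fitted-model results: estimates, posterior latent field, maps and indices.

:class:`LGCPResults` wraps the maximised parameters together with the Laplace
posterior of the latent field and turns them into the survey products:

* ``posterior_latent`` — conditional mean and variance of every cell-year,
* ``intensity_map`` — posterior mean intensity surface for a year (log-normal
  mean formula exp(m + v/2)),
* ``annual_index`` — yearly spatially-integrated abundance index with
  Monte-Carlo 95% intervals from the Laplace-Gaussian posterior,
* ``period_shift_test`` — likelihood-ratio test for a mean shift between an
  early and a late period.

Catchability terms (thermocline and, if enabled, hour of day) describe
observation efficiency, not abundance: the index and maps evaluate them at a
fixed reference (the catchability maximum), so they scale all years equally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .model import LGCPModel, LatentState, lr_test


@dataclass
class IntensityMap:
    year: int
    day: int | None
    mean: np.ndarray       # (nlat, nlon) posterior mean intensity per cell
    sd: np.ndarray         # (nlat, nlon) posterior standard deviation


class LGCPResults:
    """Result of :meth:`LGCPModel.fit`."""

    def __init__(self, model: LGCPModel, theta: np.ndarray, nll: float,
                 grad: np.ndarray, mode: dict, cov_theta: np.ndarray | None,
                 converged: bool, optimizer_result=None):
        self.model = model
        self.theta = theta
        self.params = model.unpack(theta)
        self.nll = float(nll)
        self.grad = grad
        self.mode = mode
        self.cov_theta = cov_theta
        self.converged = converged
        self.optimizer_result = optimizer_result
        self._S_inv = None

    # ------------------------------------------------------------- reporting

    @property
    def latent_mode(self) -> LatentState:
        m = self.model
        z = self.mode["z"]
        field = (z[:m.m1].reshape(m.C, m.Y) if m.config.include_field
                 else np.zeros((m.C, m.Y)))
        yearf = z[m.m1:] if m.config.include_year_effect else np.zeros(m.Y)
        return LatentState(field=field, year_effect=yearf, nugget=self.mode["eps"])

    def param_table(self) -> pd.DataFrame:
        names, values, se = self.model.raw_param_table(self.theta, self.cov_theta)
        return pd.DataFrame({"parameter": names, "estimate": values, "se": se})

    def summary(self) -> str:
        m = self.model
        tab = self.param_table()
        lines = [
            "Log-Gaussian Cox process fit (Laplace-approximated ML)",
            f"  samples: {m.n}   cells: {m.C}   years: {m.year0}-{m.year1}",
            f"  negative log-likelihood: {self.nll:.4f}",
            f"  converged: {self.converged}   max |gradient|: {np.abs(self.grad).max():.2e}",
            "",
            tab.to_string(index=False, float_format=lambda v: f"{v:.5g}"),
        ]
        p = self.params
        if p.a_spawn2 > 0:
            lines.append(f"\n  seasonal peak day: {p.seasonal_peak_day():.1f}")
        if m.config.thermocline_effect and p.a_thc2 > 0:
            lines.append(f"  catchability peak thermocline depth: {p.thermocline_peak_m():.1f} m")
        return "\n".join(lines)

    # ------------------------------------------------------ posterior latents

    @property
    def S_inv(self) -> np.ndarray:
        """Laplace posterior covariance of (field, year effect)."""
        if self._S_inv is None:
            if self.model.mz == 0:
                self._S_inv = np.zeros((0, 0))
            else:
                self._S_inv = sla.cho_solve(self.mode["cho_S"], np.eye(self.model.mz))
        return self._S_inv

    def posterior_latent(self):
        """Posterior mean and marginal variance of each cell-year log-level.

        Returns (mean, var) arrays of shape (n_cells, n_years) for the sum
        field + year effect, conditional on all data.
        """
        m = self.model
        P = self.S_inv
        mean = np.zeros((m.C, m.Y))
        var = np.zeros((m.C, m.Y))
        z = self.mode["z"]
        if m.config.include_field:
            mean += z[:m.m1].reshape(m.C, m.Y)
            var += np.diag(P)[:m.m1].reshape(m.C, m.Y)
        if m.config.include_year_effect:
            mean += z[m.m1:][None, :]
            var += np.diag(P)[m.m1:][None, :]
            if m.config.include_field:
                cross = P[:m.m1, m.m1:]                      # (C*Y, Y)
                idx = np.arange(m.m1)
                var += 2.0 * cross[idx, idx % m.Y].reshape(m.C, m.Y)
        if (var < -1e-10).any():
            raise np.linalg.LinAlgError("non-positive-definite Laplace posterior")
        return mean, np.clip(var, 0.0, None)

    def _draw_cell_year(self, n_draws: int, seed: int) -> np.ndarray:
        """Seeded draws of the cell-year log-level, shape (n_draws, C, Y)."""
        m = self.model
        rng = np.random.default_rng(seed)
        if m.mz == 0:
            return np.zeros((n_draws, m.C, m.Y))
        L = self.mode["cho_S"][0]                            # S = L L'
        xi = rng.standard_normal((m.mz, n_draws))
        dev = sla.solve_triangular(L, xi, lower=True, trans="T")
        z = self.mode["z"][:, None] + dev                    # (mz, n_draws)
        out = np.zeros((n_draws, m.C, m.Y))
        if m.config.include_field:
            out += z[:m.m1].T.reshape(n_draws, m.C, m.Y)
        if m.config.include_year_effect:
            out += z[m.m1:].T[:, None, :]
        return out

    # -------------------------------------------------------------- products

    def _seasonal_factor(self, day: int | None) -> float:
        p = self.params
        if day is not None:
            return float(np.exp(p.p_spawn(day)))
        days = np.arange(1, 366, dtype=float)
        return float(np.sum(np.exp(p.p_spawn(days))))

    def _catchability_reference(self) -> float:
        p = self.params
        if not self.model.config.thermocline_effect:
            return 1.0
        depths = np.linspace(0.0, 80.0, 801)
        return float(np.exp(p.p_thc(depths).max()))

    def _year_offsets(self) -> np.ndarray:
        """Intercept + period shift per year (log scale)."""
        m = self.model
        off = np.full(m.Y, self.params.intercept)
        if m.config.period_cut is not None and self.params.period_shift is not None:
            _, cut_after = m.config.period_cut
            off += self.params.period_shift * (m.years > cut_after)
        return off

    def intensity_map(self, year: int, day: int | None = None) -> IntensityMap:
        """Posterior mean intensity per cell for one year.

        ``day`` selects a day of year; omitted means seasonally integrated.
        Catchability is held at its reference maximum.
        """
        m = self.model
        if not (m.year0 <= year <= m.year1):
            raise ValueError(f"year {year} outside fitted range {m.year0}-{m.year1}")
        iy = year - m.year0
        mean_l, var_l = self.posterior_latent()
        log_scale = self._year_offsets()[iy] + np.log(self._seasonal_factor(day)) \
            + np.log(self._catchability_reference())
        mu = mean_l[:, iy] + log_scale
        v = var_l[:, iy]
        mean = np.exp(mu + 0.5 * v)
        sd = mean * np.sqrt(np.expm1(v))
        shape = (m.grid.nlat, m.grid.nlon)
        return IntensityMap(year=year, day=day,
                            mean=mean.reshape(shape), sd=sd.reshape(shape))

    def annual_index(self, n_draws: int = 1000, seed: int = 0,
                     day: int | None = None) -> pd.DataFrame:
        """Yearly spatially-integrated abundance index with 95% interval.

        index_y = sum_cells area_c * E[exp(eta)] integrated over the season
        (or at ``day``), catchability at its reference.  The interval comes
        from ``n_draws`` seeded draws of the Laplace-Gaussian posterior
        propagated through the same sum.
        """
        m = self.model
        area = m.grid.cell_areas_km2()
        scale = self._seasonal_factor(day) * self._catchability_reference()
        offsets = self._year_offsets()

        mean_l, var_l = self.posterior_latent()
        idx = scale * np.exp(offsets)[None, :] * area[:, None] \
            * np.exp(mean_l + 0.5 * var_l)
        index = idx.sum(axis=0)

        draws = self._draw_cell_year(n_draws, seed)          # (n_draws, C, Y)
        tot = (scale * np.exp(offsets)[None, None, :] * area[None, :, None]
               * np.exp(draws)).sum(axis=1)                  # (n_draws, Y)
        lo = np.quantile(tot, 0.025, axis=0)
        hi = np.quantile(tot, 0.975, axis=0)
        lo = np.minimum(lo, index)
        hi = np.maximum(hi, index)
        return pd.DataFrame({"year": m.years, "index": index,
                             "lo95": lo, "hi95": hi})


@dataclass
class PeriodShiftResult:
    statistic: float
    p_value: float
    mean_index_early: float
    mean_index_late: float
    shift_estimate: float
    fit_full: LGCPResults
    fit_reduced: LGCPResults


def period_shift_test(samples, grid, years, config, cut_before: int, cut_after: int,
                      start=None, index_seed: int = 0) -> PeriodShiftResult:
    """LR test for a mean shift between years < cut_before and years > cut_after.

    Intermediate years carry no offset and follow the latent year level.  The
    reduced model (no offset) must be nested in the full one; the statistic is
    referred to chi^2(1).  Also returns the mean abundance index of the two
    periods under the full fit.
    """
    years_arr = samples["year"].to_numpy()
    if not (years_arr < cut_before).any() or not (years_arr > cut_after).any():
        raise ValueError("both periods must contain data")

    cfg_full = replace(config, period_cut=(cut_before, cut_after))
    cfg_red = replace(config, period_cut=None)
    fit_red = LGCPModel(samples, grid, years, cfg_red).fit(start=start, compute_se=False)
    # warm-start the full fit at the reduced optimum (shift 0): the optimiser
    # only descends, so nesting holds numerically as well as analytically
    start_full = fit_red.params.replace(period_shift=0.0)
    fit_full = LGCPModel(samples, grid, years, cfg_full).fit(start=start_full,
                                                             compute_se=False)
    stat, p = lr_test(fit_full, fit_red, df=1)

    idx = fit_full.annual_index(seed=index_seed)
    early = idx[idx["year"] < cut_before]["index"].mean()
    late = idx[idx["year"] > cut_after]["index"].mean()
    return PeriodShiftResult(statistic=stat, p_value=p,
                             mean_index_early=float(early), mean_index_late=float(late),
                             shift_estimate=float(fit_full.params.period_shift or 0.0),
                             fit_full=fit_full, fit_reduced=fit_red)
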