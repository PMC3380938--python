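"""Structural parameters of the log-Gaussian Cox larvae model.

The latent log-intensity for sample *i* is

    eta_i = intercept
            + field(cell_i, year_i)          # space-time Gaussian field
            + year_effect(year_i)            # random yearly log-level
            + a_spawn1 * d_i - a_spawn2 * d_i**2       # seasonal (log-Gaussian) curve
            + a_thc1 * t_i - a_thc2 * t_i**2           # thermocline catchability
            + mu(hour_i)                     # optional diurnal catchability
            + period_shift * 1[year in late period]    # optional shift-test offset
            + nugget_i                       # per-sample noise

with counts Poisson(exp(eta_i)) given eta.  The quadratics are written
``a1*x - a2*x**2`` with ``a1, a2 > 0`` so positive coefficients give concave
(peaked) curves; the peak sits at ``a1 / (2*a2)``.

The space-time field is mean-zero Gaussian with separable exponential
covariance  sigma^2 * exp(-alpha*dx_km) * exp(-beta*dt_years); the year
effect has covariance sigma_y^2 * exp(-beta*dt_years); the nugget is iid
with variance sigma0^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class ModelParams:
    """All structural parameters, on the raw (uncentred) covariate scale."""

    sigma0_sq: float = 2.36       # nugget variance, log-abundance scale
    sigma_sq: float = 6.43        # space-time field variance
    sigma_y_sq: float = 1.0       # year-effect variance (not printed by the survey fit)
    log_alpha: float = -5.45      # log spatial decay rate, per km
    log_beta: float = -1.22       # log temporal decay rate, per year
    intercept: float = 0.0        # overall log-level
    a_spawn1: float = 2.41e-1     # seasonal quadratic, per day
    a_spawn2: float = 6.21e-4     # seasonal quadratic, per day^2
    a_thc1: float = 8.33e-2       # thermocline quadratic, per m
    a_thc2: float = 2.71e-3       # thermocline quadratic, per m^2
    mu_hour: np.ndarray | None = None   # 24 hour-of-day offsets (sum to zero), or None
    period_shift: float | None = None   # late-period offset on the year-effect mean

    def __post_init__(self):
        for name in ("sigma0_sq", "sigma_sq", "sigma_y_sq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mu_hour is not None:
            mu = np.asarray(self.mu_hour, dtype=float)
            if mu.shape != (24,):
                raise ValueError("mu_hour must have 24 entries")
            self.mu_hour = mu

    # -- derived quantities -------------------------------------------------

    @property
    def alpha(self) -> float:
        return float(np.exp(self.log_alpha))

    @property
    def beta(self) -> float:
        return float(np.exp(self.log_beta))

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def p_spawn(self, day):
        """Seasonal log-abundance curve p_spawn(d) = a1*d - a2*d^2."""
        day = np.asarray(day, dtype=float)
        return self.a_spawn1 * day - self.a_spawn2 * day ** 2

    def p_thc(self, depth_m):
        """Thermocline catchability curve p_thc(t) = b1*t - b2*t^2."""
        t = np.asarray(depth_m, dtype=float)
        return self.a_thc1 * t - self.a_thc2 * t ** 2

    def seasonal_peak_day(self) -> float:
        """Day of year maximising the seasonal curve (a1 / 2 a2)."""
        return self.a_spawn1 / (2.0 * self.a_spawn2)

    def thermocline_peak_m(self) -> float:
        """Thermocline depth maximising catchability (b1 / 2 b2)."""
        return self.a_thc1 / (2.0 * self.a_thc2)


def correlation_at(params: ModelParams, dx_km, dt_years):
    """Space-time correlation exp(-alpha*dx - beta*dt) of the latent field.

    Monotone non-increasing in both arguments; exactly 1 at the origin.
    """
    dx = np.asarray(dx_km, dtype=float)
    dt = np.asarray(dt_years, dtype=float)
    if (dx < 0).any() or (dt < 0).any():
        raise ValueError("distances must be non-negative")
    out = np.exp(-params.alpha * dx - params.beta * dt)
    return float(out) if out.ndim == 0 else out


def linear_predictor(params: ModelParams, latent, samples, year0: int,
                     missing_thc_policy: str = "deep", missing_thc_depth: float = 60.0):
    """Per-sample log-intensity eta_i given parameters and latent values.

    ``latent`` is a :class:`~lgcpindex.model.LatentState`; ``samples`` must
    carry cell_id, year, day_of_year, hour and thermocline_depth_m.
    ``year0`` maps calendar years to latent year indices.

    Missing thermocline values follow ``missing_thc_policy``: "deep" (default)
    treats the column as deeper than the catchability range (imputes
    ``missing_thc_depth``), "error" raises.
    """
    cell = samples["cell_id"].to_numpy()
    yi = samples["year"].to_numpy() - year0
    day = samples["day_of_year"].to_numpy(dtype=float)
    thc = samples["thermocline_depth_m"].to_numpy(dtype=float)
    if np.isnan(thc).any():
        if missing_thc_policy == "error":
            raise ValueError("missing thermocline depths and policy is 'error'")
        thc = np.where(np.isnan(thc), missing_thc_depth, thc)

    eta = (params.intercept
           + latent.field[cell, yi]
           + latent.year_effect[yi]
           + params.p_spawn(day)
           + params.p_thc(thc))
    if params.mu_hour is not None:
        eta = eta + params.mu_hour[samples["hour"].to_numpy()]
    if params.period_shift is not None and "in_late_period" in samples.columns:
        eta = eta + params.period_shift * samples["in_late_period"].to_numpy(dtype=float)
    if latent.nugget is not None:
        eta = eta + latent.nugget
    return eta
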