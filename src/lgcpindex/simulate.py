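"""Synthetic survey data from the model's own generative process.

Emulates the structure of a plankton-recorder larvae dataset: tow samples
scattered over a lat/lon grid and many years, a latent log-normal intensity
with separable space-time correlation, random yearly levels, per-sample
nugget noise, a seasonal spawning curve and thermocline-dependent
catchability, with Poisson counts on top.  Also provides smooth synthetic
thermocline fields and analytic velocity fields so the full pipeline runs
without any external data.

Default truth parameters are the published survey estimates (see
:class:`~lgcpindex.params.ModelParams` defaults); the year-effect variance
and the intercept are not printed by that fit and use package defaults
chosen to give desk-scale data with realistic sparsity (documented in the
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .backtrack import AnalyticVelocityField
from .covariance import CovarianceStructure
from .data import attach_thermocline, make_covariate_field
from .grid import GridSpec
from .model import LatentState
from .params import ModelParams

DEFAULT_TRUTH = ModelParams(intercept=-23.0)

NM_10_KM = 18.52           # one silk-band sample represents 10 nautical miles of tow


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic survey; seed-deterministic."""

    grid: GridSpec = dc_field(default_factory=lambda: GridSpec(nlat=8, nlon=8))
    years: tuple[int, int] = (1986, 2005)
    samples_per_year: int = 150
    params: ModelParams = dc_field(default_factory=lambda: DEFAULT_TRUTH)
    seed: int = 0
    design: str = "uniform"            # "uniform" | "transect"
    day_range: tuple[int, int] = (60, 300)
    thermocline: dict = dc_field(default_factory=dict)
    velocity_kind: str = "gyre"
    jitter: float = 1e-8

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @property
    def n_samples(self) -> int:
        return self.samples_per_year * self.n_years


def _seeds(config: SimulationConfig, n: int = 5):
    return np.random.SeedSequence(config.seed).spawn(n)


def simulate_design(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Sample positions, dates and hours (no counts yet)."""
    rng = rng or np.random.default_rng(_seeds(config)[0])
    g = config.grid
    n = config.n_samples
    years = np.repeat(np.arange(config.years[0], config.years[1] + 1),
                      config.samples_per_year)
    if config.design == "uniform":
        lat = rng.uniform(g.lat0, g.lat_max, n)
        lon = rng.uniform(g.lon0, g.lon_max, n)
    elif config.design == "transect":
        lat, lon = _transect_positions(config, rng)
    else:
        raise ValueError(f"unknown design {config.design!r}")
    day = rng.integers(config.day_range[0], config.day_range[1] + 1, n)
    hour = rng.integers(0, 24, n)
    return pd.DataFrame({
        "sample_id": [f"s{i:06d}" for i in range(n)],
        "lat": lat, "lon": lon, "year": years,
        "day_of_year": day, "hour": hour,
    })


def _transect_positions(config: SimulationConfig, rng):
    """Straight tow tracks with 10-nautical-mile sample spacing."""
    g = config.grid
    n = config.n_samples
    lats, lons = [], []
    dlat_step = NM_10_KM / 111.19
    while len(lats) < n:
        la = rng.uniform(g.lat0, g.lat_max)
        lo = rng.uniform(g.lon0, g.lon_max)
        heading = rng.uniform(0, 2 * np.pi)
        for _ in range(rng.integers(10, 40)):
            if g.contains(la, lo):
                lats.append(la); lons.append(lo)
            la += dlat_step * np.cos(heading)
            lo += dlat_step * np.sin(heading) / np.cos(np.deg2rad(la))
            if not g.contains(la, lo):
                break
    return np.array(lats[:n]), np.array(lons[:n])


def simulate_latent(config: SimulationConfig, n_nugget: int | None = None,
                    rng=None) -> LatentState:
    """Draw the latent Gaussian components under ``config.params``.

    Field: sigma^2 * exp(-alpha dx - beta dt) over cells x years (drawn via
    the Kronecker square root L_s Z L_t'); year effect: sigma_y^2 *
    exp(-beta dt); nugget: iid sigma_0^2 per sample.
    """
    p = config.params
    if p.sigma_sq < 0 or p.sigma_y_sq < 0 or p.sigma0_sq < 0:
        raise ValueError("variances must be non-negative")
    rng = rng or np.random.default_rng(_seeds(config)[2])
    g = config.grid
    Y = config.n_years
    n = n_nugget if n_nugget is not None else config.n_samples

    cov = CovarianceStructure(p, g.distance_matrix_km(), Y, config.jitter)
    Z = rng.standard_normal((g.n_cells, Y))
    field = np.sqrt(p.sigma_sq) * cov.Ls @ Z @ cov.Lt.T
    year = np.sqrt(p.sigma_y_sq) * cov.Lt @ rng.standard_normal(Y)
    nug = np.sqrt(p.sigma0_sq) * rng.standard_normal(n)
    return LatentState(field=field, year_effect=year, nugget=nug)


def simulate_survey(latent: LatentState, config: SimulationConfig,
                    design: pd.DataFrame | None = None, rng=None,
                    eta_max: float = 30.0) -> pd.DataFrame:
    """Poisson counts at designed samples given the latent state.

    ``design`` must carry cell_id and thermocline_depth_m (a constant default
    of the catchability-peak depth is used when absent, so pure count checks
    need no covariate field).  Raises if any log-intensity exceeds
    ``eta_max`` (advice: rescale the intercept).
    """
    from .data import assign_cells
    from .params import linear_predictor

    rng = rng or np.random.default_rng(_seeds(config)[3])
    design = design if design is not None else simulate_design(config)
    if "cell_id" not in design.columns:
        design = assign_cells(design, config.grid)
    if "thermocline_depth_m" not in design.columns:
        design = design.assign(thermocline_depth_m=config.params.thermocline_peak_m()
                               if config.params.a_thc2 > 0 else 0.0)
    if "in_late_period" not in design.columns and config.params.period_shift is not None:
        raise ValueError("params.period_shift set but design lacks 'in_late_period'")

    eta = linear_predictor(config.params, latent, design, year0=config.years[0])
    if (eta > eta_max).any():
        raise ValueError(
            f"log-intensity exceeds {eta_max} (max {eta.max():.1f}); "
            "rescale the intercept or variances")
    out = design.copy()
    out["count"] = rng.poisson(np.exp(eta))
    return out


def simulate_thermocline(grid: GridSpec, months, settings=None, seed: int = 0):
    """Smooth synthetic monthly thermocline-depth field on a fine grid.

    Seasonal sinusoid (shallowest in late summer) + south-north gradient +
    smooth random spatial noise, clipped to [5, 80] m.  ``months`` is a
    sequence of (year, month) pairs.  ``settings`` keys: base_m, seasonal_amp,
    lat_gradient_m_per_deg, noise_amp, dlat, dlon, mask_box.
    """
    s = {"base_m": 35.0, "seasonal_amp": 15.0, "lat_gradient_m_per_deg": 1.5,
         "noise_amp": 4.0, "dlat": 0.1, "dlon": 1.0 / 6.0, "mask_box": None}
    s.update(settings or {})
    rng = np.random.default_rng(seed)

    lats = np.arange(grid.lat0, grid.lat_max + 1e-9, s["dlat"])
    lons = np.arange(grid.lon0, grid.lon_max + 1e-9, s["dlon"])
    LA, LO = np.meshgrid(lats, lons, indexing="ij")

    # smooth noise: a few random long-wavelength harmonics, fixed per field
    noise = np.zeros_like(LA)
    for _ in range(4):
        kx, ky = rng.uniform(0.2, 1.0, 2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        noise += np.sin(kx * LO + ph1) * np.sin(ky * LA + ph2)
    noise *= s["noise_amp"] / 2.0

    vals = np.empty((len(months), len(lats), len(lons)))
    for k, (yr, mo) in enumerate(months):
        seasonal = -s["seasonal_amp"] * np.cos(2 * np.pi * (mo - 8) / 12.0)
        vals[k] = s["base_m"] + seasonal + s["lat_gradient_m_per_deg"] * (LA - grid.lat0) \
            + noise
    vals = np.clip(vals, 5.0, 80.0)
    if s["mask_box"] is not None:
        la0, la1, lo0, lo1 = s["mask_box"]
        m = (LA >= la0) & (LA <= la1) & (LO >= lo0) & (LO <= lo1)
        vals[:, m] = np.nan
    return make_covariate_field(vals, lats, lons, list(months))


def make_velocity_field(kind: str, grid: GridSpec | None = None, **params):
    """Analytic velocity field fixture (still / uniform / solid_rotation / gyre)."""
    if kind == "gyre" and grid is not None:
        params.setdefault("lat_bounds", (grid.lat0, grid.lat_max))
        params.setdefault("lon_bounds", (grid.lon0, grid.lon_max))
    if kind == "solid_rotation" and grid is not None:
        params.setdefault("center_lat", 0.5 * (grid.lat0 + grid.lat_max))
        params.setdefault("center_lon", 0.5 * (grid.lon0 + grid.lon_max))
    return AnalyticVelocityField(kind, **params)


def simulate_dataset(config: SimulationConfig):
    """Full generative pipeline: design -> thermocline -> latent -> counts.

    Returns (samples, latent, thermocline_field).  Deterministic given
    (config, config.seed); all stage RNGs are spawned from the single seed.
    """
    from .data import assign_cells

    ss = _seeds(config)
    design = simulate_design(config, np.random.default_rng(ss[0]))
    design = assign_cells(design, config.grid)

    months = [(y, m) for y in range(config.years[0], config.years[1] + 1)
              for m in range(1, 13)]
    thc_seed = int(ss[1].generate_state(1)[0] % (2 ** 31))
    field = simulate_thermocline(config.grid, months, config.thermocline, seed=thc_seed)
    design = attach_thermocline(design, field)

    latent = simulate_latent(config, n_nugget=len(design),
                             rng=np.random.default_rng(ss[2]))
    if config.params.period_shift is not None:
        raise ValueError("use a 'period_shift_years' aware helper; see simulate_shifted")
    samples = simulate_survey(latent, config, design, rng=np.random.default_rng(ss[3]))
    return samples, latent, field


def simulate_shifted(config: SimulationConfig, cut_after: int, shift: float):
    """Like :func:`simulate_dataset` with a late-period offset on the year mean.

    Years > ``cut_after`` get ``shift`` added to the log-level (e.g.
    shift = -log(4) simulates a 4-fold drop).
    """
    from .data import assign_cells

    ss = _seeds(config)
    design = simulate_design(config, np.random.default_rng(ss[0]))
    design = assign_cells(design, config.grid)
    months = [(y, m) for y in range(config.years[0], config.years[1] + 1)
              for m in range(1, 13)]
    thc_seed = int(ss[1].generate_state(1)[0] % (2 ** 31))
    field = simulate_thermocline(config.grid, months, config.thermocline, seed=thc_seed)
    design = attach_thermocline(design, field)
    design["in_late_period"] = (design["year"] > cut_after).astype(float)

    latent = simulate_latent(config, n_nugget=len(design),
                             rng=np.random.default_rng(ss[2]))
    shifted = config.params.replace(period_shift=shift)
    cfg = SimulationConfig(**{**config.__dict__, "params": shifted})
    samples = simulate_survey(latent, cfg, design, rng=np.random.default_rng(ss[3]))
    return samples, latent, field
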