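"""Sample tables and gridded covariate fields.

A *sample table* is a pandas DataFrame with one row per silk-band sample:

======================  =======================================================
column                  meaning
======================  =======================================================
``sample_id``           unique token
``lat``, ``lon``        tow midpoint, decimal degrees
``year``                calendar year
``day_of_year``         1–366
``hour``                0–23
``count``               non-negative integer larvae count
``thermocline_depth_m`` metres, positive down; NaN = undefined / mixed column
``cell_id``             grid-cell index under the active :class:`GridSpec`
======================  =======================================================

Covariate fields (e.g. monthly thermocline depth) are ``xarray.DataArray``
objects with dimensions ``(time, lat, lon)`` on a regular grid; NaN marks
masked (mixed-column) nodes.  NetCDF I/O uses the classic format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec

REQUIRED_COLUMNS = ["sample_id", "lat", "lon", "year", "day_of_year", "hour", "count"]
OPTIONAL_COLUMNS = ["thermocline_depth_m", "cell_id"]


class SchemaError(ValueError):
    """Raised when a sample file is missing mandatory columns."""


def validate_samples(df: pd.DataFrame,
                     lat_bounds: tuple[float, float] = (51.0, 61.0),
                     lon_bounds: tuple[float, float] = (-3.5, 9.5)) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw table into (valid rows, rejected rows with a reason column).

    Checks: integer non-negative counts, day-of-year in 1..366, hour in 0..23,
    position within the configured study bounds.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    df = df.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, why):
        nonlocal reasons
        mask = mask.fillna(True) if hasattr(mask, "fillna") else mask
        reasons[mask & (reasons == "")] = why

    count_num = pd.to_numeric(df["count"], errors="coerce")
    flag(count_num.isna() | (count_num != np.floor(count_num)), "non-integer count")
    flag(count_num < 0, "negative count")
    doy = pd.to_numeric(df["day_of_year"], errors="coerce")
    flag(doy.isna() | (doy < 1) | (doy > 366), "day_of_year outside 1..366")
    hour = pd.to_numeric(df["hour"], errors="coerce")
    flag(hour.isna() | (hour < 0) | (hour > 23), "hour outside 0..23")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    flag(lat.isna() | (lat < lat_bounds[0]) | (lat > lat_bounds[1]), "latitude outside study bounds")
    flag(lon.isna() | (lon < lon_bounds[0]) | (lon > lon_bounds[1]), "longitude outside study bounds")

    bad = reasons != ""
    rejected = df[bad].assign(reason=reasons[bad])
    good = df[~bad].copy()
    good["count"] = count_num[~bad].astype(int)
    good["year"] = good["year"].astype(int)
    good["day_of_year"] = doy[~bad].astype(int)
    good["hour"] = hour[~bad].astype(int)
    for c in ("lat", "lon"):
        good[c] = good[c].astype(float)
    if "thermocline_depth_m" not in good.columns:
        good["thermocline_depth_m"] = np.nan
    return good.reset_index(drop=True), rejected


def read_samples(path, lat_bounds=(51.0, 61.0), lon_bounds=(-3.5, 9.5),
                 sep=",", on_invalid="warn") -> pd.DataFrame:
    """Read a delimited sample file, validate rows, return the valid table.

    ``on_invalid``: "warn" (default) reports rejected rows via a warning,
    "error" raises, "silent" drops quietly.
    """
    raw = pd.read_csv(path, sep=sep)
    good, rejected = validate_samples(raw, lat_bounds, lon_bounds)
    if len(rejected):
        msg = (f"{len(rejected)} row(s) rejected:\n"
               + rejected[["sample_id", "reason"]].to_string(index=False))
        if on_invalid == "error":
            raise ValueError(msg)
        if on_invalid == "warn":
            import warnings
            warnings.warn(msg, stacklevel=2)
    return good


def write_samples(df: pd.DataFrame, path, sep=",") -> None:
    """Write a sample table as delimited text with a header (round-trip safe)."""
    out = df.copy()
    for c in ("lat", "lon", "thermocline_depth_m"):
        if c in out.columns:
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep=sep, index=False)


def assign_cells(samples: pd.DataFrame, grid: GridSpec, on_outside="warn") -> pd.DataFrame:
    """Attach ``cell_id`` for each sample's midpoint; drop out-of-grid samples.

    Half-open convention: a point on a shared edge belongs to the cell whose
    lower edge it lies on.  Idempotent.
    """
    samples = samples.copy()
    cell = grid.cell_of(samples["lat"].to_numpy(), samples["lon"].to_numpy())
    outside = cell < 0
    if outside.any():
        msg = f"{int(outside.sum())} sample(s) outside the grid were excluded"
        if on_outside == "error":
            raise ValueError(msg)
        if on_outside == "warn":
            import warnings
            warnings.warn(msg, stacklevel=2)
    samples["cell_id"] = cell
    return samples[~outside].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gridded covariate fields


def make_covariate_field(values: np.ndarray, lats: np.ndarray, lons: np.ndarray,
                         times, name: str = "thermocline_depth_m") -> xr.DataArray:
    """Wrap a (time, lat, lon) array as a covariate field.

    ``times`` is a sequence of (year, month) pairs or datetime-likes; the time
    axis must be strictly increasing.
    """
    stamps = []
    for t in times:
        if isinstance(t, tuple):
            y, m = t
            stamps.append(np.datetime64(f"{y:04d}-{m:02d}-15"))
        else:
            stamps.append(np.datetime64(t))
    times = np.asarray(stamps)
    if not (np.diff(times) > np.timedelta64(0, "s")).all():
        raise ValueError("time axis must be strictly increasing")
    da = xr.DataArray(np.asarray(values, dtype=float),
                      dims=("time", "lat", "lon"),
                      coords={"time": times, "lat": np.asarray(lats, float),
                              "lon": np.asarray(lons, float)},
                      name=name)
    return da


def write_field(da: xr.DataArray, path) -> None:
    """Write a gridded field as classic NetCDF (CF-style lat/lon/time)."""
    da.to_netcdf(path, engine="scipy")


def read_field(path, name=None) -> xr.DataArray:
    ds = xr.open_dataset(path, engine="scipy")
    if name is None:
        name = list(ds.data_vars)[0]
    return ds[name].load()


def attach_thermocline(samples: pd.DataFrame, field: xr.DataArray) -> pd.DataFrame:
    """Look up thermocline depth at the nearest grid node, exact calendar month.

    Samples falling on masked (NaN) nodes keep the missing marker (NaN), not
    zero.  Raises if any sample's (year, month) is outside the field's time
    axis, listing the offending years.
    """
    samples = samples.copy()
    # month from day-of-year (non-leap convention; monthly fields are coarse)
    month_edges = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334, 366])
    month = np.searchsorted(month_edges, samples["day_of_year"].to_numpy(), side="left")
    month = np.clip(month, 1, 12)

    t_index = pd.to_datetime(field["time"].values)
    key = t_index.year * 100 + t_index.month
    lookup = {k: i for i, k in enumerate(key)}
    want = samples["year"].to_numpy() * 100 + month
    missing_years = sorted({w // 100 for w in want if w not in lookup})
    if missing_years:
        raise ValueError(f"sample dates outside covariate time axis for year(s): {missing_years}")
    ti = np.array([lookup[w] for w in want])

    lat_ax = field["lat"].values
    lon_ax = field["lon"].values
    li = np.abs(samples["lat"].to_numpy()[:, None] - lat_ax[None, :]).argmin(axis=1)
    lj = np.abs(samples["lon"].to_numpy()[:, None] - lon_ax[None, :]).argmin(axis=1)
    samples["thermocline_depth_m"] = field.values[ti, li, lj]
    return samples
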