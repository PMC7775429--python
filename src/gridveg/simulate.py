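"""Synthetic study regions with known, planted climate-vegetation coupling.

The generator emulates the data situation of a remote dryland study region:
a fine-grid sub-monthly NDVI cube, several monthly climate "products" on
coarser grids that all observe one shared latent climate truth with
product-specific corruption, a gappy daily snow-index cube, and a vegetation
class raster.  One (product, variable, window) combination is the *planted
driver*: the regional NDVI peak anomaly is a linear response to that
driver's window anomaly, plus a shared regional residual and independent
pixel noise, with the response removed inside a contiguous *decoupled zone*
(emulating valley/irrigation decoupling).

The latent monthly anomalies of every variable are i.i.d. standard normal;
the planted driver signal is the (scaled) mean of the latent months inside
the planted window, so the planted window is by construction the cleanest
measurement of the signal while sub- or super-windows of the same variable
correlate with it only through month overlap.  Products observe the latent
months with a fidelity weight plus year-persistent and purely monthly noise;
a fidelity of zero yields the "unsuitable" product whose interannual
variation carries no truth at all.

The area-level Pearson correlation between the NDVI area anomaly and the
driver signal is calibrated analytically: with coupled fraction c of the N
analyzed pixels and pixel noise SD sigma_p, the shared-residual SD sigma_a
is solved from  r^2 = c^2 / (c^2 + sigma_a^2 + sigma_p^2 / N).
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .anomalies import DEFAULT_WINDOWS, SeasonWindow
from .cubes import ClassRaster, ClimateCube, GridSpec, TimeAxis, VEGETATION_CLASSES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProductSpec:
    """One pseudo-product: which variables it carries and how corrupted it is.

    ``fidelity`` is the weight on the shared latent anomaly (1 = perfect,
    0 = interannually unrelated); ``year_bias_frac`` splits the residual
    variance between a year-persistent bias (which survives window averaging)
    and purely monthly noise (which largely averages out).
    """

    name: str
    variables: tuple[str, ...]
    coarsening: int = 10
    fidelity: float = 0.95
    year_bias_frac: float = 0.0
    spatial_noise_sd: float = 0.2
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.coarsening < 1:
            raise ValueError("coarsening factor must be >= 1")
        if not 0 <= self.fidelity <= 1:
            raise ValueError("fidelity must be in [0, 1]")


DEFAULT_PRODUCTS: tuple[ProductSpec, ...] = (
    # a faithful reanalysis-like product (carries the planted driver)
    ProductSpec("reanalysis_a", ("precipitation", "temperature"),
                coarsening=12, fidelity=0.97, year_bias_frac=0.0),
    # a moderately corrupted product: year-persistent errors
    ProductSpec("reanalysis_b", ("precipitation",),
                coarsening=6, fidelity=0.6, year_bias_frac=0.64),
    # an unsuitable gauge-style product: plausible climate, unrelated anomalies
    ProductSpec("gauge_np", ("precipitation",),
                coarsening=20, fidelity=0.0, year_bias_frac=0.64),
)


@dataclass
class WorldConfig:
    """Study conditions of a synthetic region (defaults: 18 years, 60x60)."""

    seed: int = 0
    years: int = 18
    start_year: int = 2001
    ndvi_grid: GridSpec = field(default_factory=lambda: GridSpec(60, 60, 1.0))
    product_specs: tuple[ProductSpec, ...] = DEFAULT_PRODUCTS
    planted_driver: tuple[str, str, str] = ("reanalysis_a", "precipitation", "hydrological_year")
    effect_size: float = 0.85
    pixel_noise_sd: float = 0.6
    area_noise_sd: float | None = None      # None -> calibrated from effect_size
    null_area_noise_sd: float = 0.15        # shared residual when effect_size = 0
    decoupled_fraction: float = 0.2
    nonveg_fraction: float = 0.1
    peak_months: tuple[int, ...] = (7, 8)
    ndvi_gain: float = 0.05                 # NDVI units per unit driver anomaly
    region: str = "synthetic"
    # daily snow cube
    with_snow: bool = True
    snow_coarsening: int = 2
    snow_missing_rate: float = 0.25
    snow_cloud_persistence: float = 2 / 3   # P(cloud stays cloud next day)
    snow_coupling: float = 0.5              # corr of snow-year anomaly with driver
    n_bad_snow_pixels: int = 2              # pixels pushed over the exclusion rule

    def __post_init__(self) -> None:
        if self.years < 5:
            raise ValueError("need at least 5 years")
        if not 0 <= self.effect_size < 1:
            raise ValueError("effect_size must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth stored with every generated world."""

    driver_feature_id: str
    effect_size: float
    realized_r: float
    driver_signal: np.ndarray               # a_t per analysis year (unit variance)
    decoupled_mask: np.ndarray
    analyzed_mask: np.ndarray
    noise_params: dict


@dataclass
class World:
    config: WorldConfig
    ndvi: ClimateCube                        # sixteen_day
    climate: dict[tuple[str, str], ClimateCube]   # monthly, coarse grids
    snow_daily: ClimateCube | None
    classes: ClassRaster
    truth: TruthRecord


def _window_by_name(name: str) -> SeasonWindow:
    for w in DEFAULT_WINDOWS:
        if w.name == name:
            return w
    raise KeyError(name)


def _coarse_grid(fine: GridSpec, k: int) -> GridSpec:
    return GridSpec(
        math.ceil(fine.n_rows / k), math.ceil(fine.n_cols / k),
        fine.cell_size * k, fine.origin_x, fine.origin_y, fine.crs_label,
    )


def _climatology(variable: str, months: np.ndarray) -> np.ndarray:
    """Plausible seasonal means so cubes look like real fields (anomalies
    are unaffected: the pipeline removes the across-year mean)."""
    phase = 2 * np.pi * (months - 1) / 12
    if variable == "temperature":
        return 5.0 + 14.0 * -np.cos(phase)          # winter cold, summer warm
    if variable in ("soil_water", "skin_reservoir"):
        return 0.25 + 0.08 * np.sin(phase)
    if variable == "snow":
        return np.clip(40.0 * np.cos(phase), 0, None)
    return 30.0 + 18.0 * np.sin(phase + np.pi / 2)  # precipitation-like


def make_class_raster(cfg: WorldConfig) -> tuple[ClassRaster, np.ndarray]:
    """Band-structured class map; the decoupled zone is the valley band.

    Bottom rows (``decoupled_fraction``) are riparian valley floor, top rows
    (``nonveg_fraction``) are non-vegetated; the interior splits between
    dwarf-shrub steppe and alpine grassland.  Returns the raster and the
    decoupled-zone mask (the riparian band).
    """
    g = cfg.ndvi_grid
    ids = np.empty(g.shape, dtype=int)
    n_rip = max(1, int(round(cfg.decoupled_fraction * g.n_rows)))
    n_nonveg = int(round(cfg.nonveg_fraction * g.n_rows))
    mid = g.n_rows - n_rip - n_nonveg
    ids[:] = VEGETATION_CLASSES.index("dwarf_shrub_steppe")
    ids[: mid // 2 + n_nonveg] = VEGETATION_CLASSES.index("alpine_grassland")
    if n_nonveg:
        ids[:n_nonveg] = VEGETATION_CLASSES.index("non_vegetated")
    ids[g.n_rows - n_rip:] = VEGETATION_CLASSES.index("riparian")
    decoupled = np.zeros(g.shape, dtype=bool)
    decoupled[g.n_rows - n_rip:] = True
    return ClassRaster(g, ids), decoupled


def _calibrate_area_noise(
    cfg: WorldConfig, c: float, n_analyzed: int, signal_sd: float
) -> float:
    """Solve the shared-residual SD from the correlation identity.

    Calibrated conditionally on the realized SD of the drawn driver signal,
    so the planted area correlation is centered on the target for every
    world rather than only on average over worlds.
    """
    if cfg.area_noise_sd is not None:
        return cfg.area_noise_sd
    if cfg.effect_size == 0:
        return cfg.null_area_noise_sd
    r2 = cfg.effect_size**2
    s2 = c * c * signal_sd * signal_sd
    var_needed = s2 * (1.0 / r2 - 1.0) - cfg.pixel_noise_sd**2 / n_analyzed
    if var_needed <= 0:
        r_max = math.sqrt(s2 / (s2 + cfg.pixel_noise_sd**2 / n_analyzed))
        raise ValueError(
            f"effect_size {cfg.effect_size} infeasible with pixel_noise_sd "
            f"{cfg.pixel_noise_sd}; attainable area r <= {r_max:.4f}"
        )
    return math.sqrt(var_needed)


def make_world(cfg: WorldConfig) -> World:
    """Generate a full synthetic region (see module docstring for the model)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    clim_start = cfg.start_year - 2
    n_months = (cfg.years + 2) * 12
    month_axis = TimeAxis.monthly(clim_start, 1, n_months)
    month_nums = month_axis.months
    years = np.arange(cfg.start_year, cfg.start_year + cfg.years)

    # latent monthly anomalies, one series per variable
    variables = sorted({v for p in cfg.product_specs for v in p.variables})
    latent = {v: rng.standard_normal(n_months) for v in variables}

    # planted driver signal: scaled mean of the latent months in the window
    dr_prod, dr_var, dr_win_name = cfg.planted_driver
    window = _window_by_name(dr_win_name)
    if dr_var not in latent:
        raise ValueError(f"planted variable {dr_var!r} not carried by any product")
    if not any(p.name == dr_prod for p in cfg.product_specs):
        raise ValueError(f"planted product {dr_prod!r} not in product_specs")
    k_w = len(window.months)
    month_index = {}
    for i, (y, m, _) in enumerate(month_axis.labels):
        month_index[(y, m)] = i
    a = np.empty(cfg.years)
    for i, y in enumerate(years):
        idx = [month_index[(int(y) + off, m)] for off, m in window.months]
        a[i] = math.sqrt(k_w) * latent[dr_var][idx].mean()

    # class raster, masks, calibration
    classes, decoupled = make_class_raster(cfg)
    analyzed = classes.mask_for(frozenset(VEGETATION_CLASSES[:3]))
    coupled = analyzed & ~decoupled
    n_analyzed = int(analyzed.sum())
    c = float(coupled.sum() / n_analyzed)
    sigma_a = _calibrate_area_noise(cfg, c, n_analyzed, float(a.std()))
    slope = 0.0 if cfg.effect_size == 0 else 1.0

    # climate product cubes (monthly, coarse grids)
    climate: dict[tuple[str, str], ClimateCube] = {}
    for spec in cfg.product_specs:
        grid = _coarse_grid(cfg.ndvi_grid, spec.coarsening)
        for var in spec.variables:
            lam = spec.fidelity
            resid = math.sqrt(max(0.0, 1 - lam * lam))
            w_year = math.sqrt(spec.year_bias_frac)
            w_month = math.sqrt(1 - spec.year_bias_frac)
            year_bias = rng.standard_normal(cfg.years + 2)
            year_of_month = month_axis.years - clim_start
            regional = (
                _climatology(var, month_nums)
                + spec.bias
                + lam * latent[var]
                + resid * (w_year * year_bias[year_of_month]
                           + w_month * rng.standard_normal(n_months))
            )
            spatial = spec.spatial_noise_sd * rng.standard_normal(
                (n_months, grid.n_rows, grid.n_cols))
            values = regional[:, None, None] + spatial
            climate[(spec.name, var)] = ClimateCube(spec.name, var, grid,
                                                    month_axis, values)

    # NDVI sixteen-day cube
    g = cfg.ndvi_grid
    ndvi_axis = TimeAxis.sixteen_day(cfg.start_year, cfg.years)
    doy = np.array([
        ( _dt.date(y, m, d) - _dt.date(y, 1, 1)).days + 1
        for y, m, d in ndvi_axis.labels
    ])
    comp_year = ndvi_axis.years
    comp_month = ndvi_axis.months
    base = np.select(
        [classes.class_id == i for i in range(4)],
        [0.45, 0.25, 0.35, 0.05],
    )
    amp = np.select([classes.class_id == i for i in range(4)],
                    [0.30, 0.20, 0.25, 0.0])
    bump = np.exp(-(((doy - 210) / 60.0) ** 2))
    eta = sigma_a * rng.standard_normal(cfg.years)
    eps = cfg.pixel_noise_sd * rng.standard_normal((cfg.years,) + g.shape)
    eps[:, ~analyzed] = 0.0
    year_term = np.zeros((cfg.years,) + g.shape)
    for i in range(cfg.years):
        year_term[i] = cfg.ndvi_gain * (
            slope * a[i] * coupled + eta[i] * analyzed + eps[i])
    in_peak = np.isin(comp_month, cfg.peak_months)
    values = base[None, :, :] + amp[None, :, :] * bump[:, None, None]
    values = values + 0.01 * rng.standard_normal(values.shape) * (~in_peak)[:, None, None]
    yidx = comp_year - cfg.start_year
    values = values + year_term[yidx] * in_peak[:, None, None]
    ndvi = ClimateCube("modis_ndvi", "ndvi", g, ndvi_axis, values)

    # daily snow cube with autocorrelated gaps
    snow_daily = None
    if cfg.with_snow:
        snow_daily = _make_snow_daily(cfg, rng, latent[dr_var] if dr_var in latent
                                      else rng.standard_normal(n_months),
                                      month_index)

    # realized area-level r, computed from the generated arrays
    area_ndvi = np.array([
        (base + year_term[i])[analyzed].mean() for i in range(cfg.years)
    ])
    driver_cube = climate[(dr_prod, dr_var)]
    feat = np.empty(cfg.years)
    for i, y in enumerate(years):
        idx = [month_index[(int(y) + off, m)] for off, m in window.months]
        feat[i] = driver_cube.values[idx].mean()
    realized_r = float(np.corrcoef(area_ndvi, feat)[0, 1]) if cfg.effect_size else float(
        np.corrcoef(area_ndvi, a)[0, 1])

    truth = TruthRecord(
        driver_feature_id=f"{dr_prod}:{dr_var}/{dr_win_name}",
        effect_size=cfg.effect_size,
        realized_r=realized_r,
        driver_signal=a,
        decoupled_mask=decoupled,
        analyzed_mask=analyzed,
        noise_params={
            "sigma_area": sigma_a, "sigma_pixel": cfg.pixel_noise_sd,
            "coupled_fraction": c, "n_analyzed": n_analyzed,
            "ndvi_gain": cfg.ndvi_gain,
        },
    )
    logger.info("world seed=%s: planted %s, realized area r=%.3f",
                cfg.seed, truth.driver_feature_id, realized_r)
    return World(cfg, ndvi, climate, snow_daily, classes, truth)


def _make_snow_daily(
    cfg: WorldConfig, rng: np.random.Generator,
    driver_latent: np.ndarray, month_index: dict,
) -> ClimateCube:
    """Daily NDSI cube (0-100) with a seasonal curve, winter anomalies tied to
    the driver's winter months, and Markov-persistent cloud gaps."""
    grid = _coarse_grid(cfg.ndvi_grid, cfg.snow_coarsening)
    first = cfg.start_year - 2
    n_years_total = cfg.years + 2
    axis = TimeAxis.daily_years(first, n_years_total)
    n_days = len(axis)
    labels = axis.labels
    doy = np.array([(_dt.date(y, m, d) - _dt.date(y, 1, 1)).days + 1
                    for y, m, d in labels])
    years_arr = axis.years
    months_arr = axis.months

    # snow-year anomaly: couple to the mean winter-month latent of the driver
    nu = np.empty(n_years_total + 1)
    cc = cfg.snow_coupling
    for j in range(n_years_total + 1):
        y = first + j
        idx = [month_index.get((y - 1, m)) for m in (11, 12)]
        idx += [month_index.get((y, m)) for m in (1, 2, 3, 4)]
        idx = [i for i in idx if i is not None]
        wint = math.sqrt(len(idx)) * driver_latent[idx].mean() if idx else 0.0
        nu[j] = cc * wint + math.sqrt(1 - cc * cc) * rng.standard_normal()

    # seasonal NDSI: high in winter, zero in summer (smooth cosine ramp)
    seasonal = np.clip(45.0 * np.cos(2 * np.pi * (doy - 15) / 365.25) + 25.0, 0, 100)
    # snow year of a day: Jul..Jun belongs to the year it ends in
    snow_year = years_arr + (months_arr >= 7).astype(int) - first
    winter_weight = np.clip((seasonal - 5.0) / 65.0, 0, 1)
    regional = seasonal + 18.0 * nu[snow_year] * winter_weight
    values = regional[:, None, None] + 4.0 * rng.standard_normal(
        (n_days, grid.n_rows, grid.n_cols))
    values = np.clip(values, 0.0, 100.0)

    # Markov cloud gaps: stationary rate snow_missing_rate, persistent runs
    p_stay = cfg.snow_cloud_persistence
    pi = cfg.snow_missing_rate
    p_enter = pi * (1 - p_stay) / (1 - pi)
    n_pix = grid.n_pixels
    missing = np.empty((n_days, n_pix), dtype=bool)
    state = rng.random(n_pix) < pi
    u = rng.random((n_days, n_pix))
    for t in range(n_days):
        missing[t] = state
        state = np.where(state, u[t] < p_stay, u[t] < p_enter)
    missing = missing.reshape(n_days, grid.n_rows, grid.n_cols)
    if cfg.n_bad_snow_pixels:
        flat = rng.choice(n_pix, size=min(cfg.n_bad_snow_pixels, n_pix), replace=False)
        rr, cc_idx = np.unravel_index(flat, grid.shape)
        n_force = int(0.7 * n_days)
        missing[:n_force, rr, cc_idx] = True
    valid = ~missing
    values = np.where(valid, values, np.nan)
    return ClimateCube("modis_snow", "ndsi", grid, axis, values, valid)


def make_null_catalog(
    n_features: int = 156, years: int = 18, seed: int | np.random.Generator | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """I.i.d. standard-normal feature matrix and independent response.

    Both are mean-centered per series; supports FDR and importance null
    calibration.  Returns ``(X, y)`` with ``X`` of shape (years, n_features).
    """
    if n_features < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((years, n_features))
    y = rng.standard_normal(years)
    X = X - X.mean(axis=0, keepdims=True)
    y = y - y.mean()
    return X, y
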