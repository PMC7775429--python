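"""Seasonal windows, yearly window aggregates, anomalies and the feature catalog.

A *feature* is one (product, variable, season window) combination turned into
an area-averaged, mean-zero anomaly series with one value per analysis year
(optionally with the per-pixel anomaly matrix alongside).  Windows may reach
into the previous calendar year (the hydrological year of year Y spans
Jul(Y-1)..Jun(Y)) and each window also exists as a two-year variant that
averages the aggregates of year t and year t-1 before centering.  Anomalies
always use the across-year mean of all analysis years as the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cubes import ClimateCube, TimeAxis

logger = logging.getLogger(__name__)

SNOW_VARIABLES = frozenset({"ndsi", "fsc", "scd"})


@dataclass(frozen=True)
class SeasonWindow:
    """Named month window; offsets are relative to the anomaly's year."""

    name: str
    months: tuple[tuple[int, int], ...]  # (year_offset in {-1, 0}, month)
    two_year: bool = False

    def __post_init__(self) -> None:
        if not self.months:
            raise ValueError("window must contain at least one month")
        for off, m in self.months:
            if off not in (-1, 0) or not 1 <= m <= 12:
                raise ValueError(f"invalid window month {(off, m)}")

    @property
    def label(self) -> str:
        return self.name + ("^2yr" if self.two_year else "")

    def as_two_year(self) -> "SeasonWindow":
        return SeasonWindow(self.name, self.months, two_year=True)

    def contains_month(self, month: int) -> bool:
        return any(m == month for _, m in self.months)


def _months(spec: str) -> tuple[tuple[int, int], ...]:
    table = {
        "hydrological_year": [(-1, m) for m in range(7, 13)] + [(0, m) for m in range(1, 7)],
        "winter_half": [(-1, 11), (-1, 12)] + [(0, m) for m in range(1, 5)],
        "spring": [(0, 3), (0, 4), (0, 5)],
        "transition": [(0, 2), (0, 3)],
        "summer": [(0, 6), (0, 7), (0, 8)],
        "spring_summer": [(0, m) for m in range(3, 9)],
    }
    return tuple(table[spec])


#: The six seasonal windows used by default, mirroring a cold-dryland study
#: design: hydrological year Jul..Jun, winter half-year Nov..Apr, spring
#: Mar..May, winter-spring transition Feb..Mar, summer Jun..Aug and the
#: combined spring-summer Mar..Aug.
DEFAULT_WINDOWS: tuple[SeasonWindow, ...] = tuple(
    SeasonWindow(name, _months(name))
    for name in ("hydrological_year", "winter_half", "spring", "transition",
                 "summer", "spring_summer")
)

#: Windows never paired with snow variables (they include summer months).
SNOW_EXCLUDED_WINDOWS = frozenset({"summer", "spring_summer"})


@dataclass
class FeatureSeries:
    """One (product, variable, window) anomaly series; the unit of testing."""

    product: str
    variable: str
    window: SeasonWindow
    years: np.ndarray
    anomaly: np.ndarray
    pixel_anomaly: np.ndarray | None = None      # (n_years, n_pixels)
    pixel_mask: np.ndarray | None = None         # (rows, cols) bool
    dropped_years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.anomaly = np.asarray(self.anomaly, dtype=float)
        if self.years.shape != self.anomaly.shape:
            raise ValueError("years/anomaly length mismatch")
        if not np.allclose(self.anomaly.mean(), 0.0, atol=1e-8):
            raise ValueError("anomaly series must be mean-zero")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")

    @property
    def feature_id(self) -> str:
        return f"{self.product}:{self.variable}/{self.window.label}"

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass
class NdviAnomalySeries:
    """Annual vegetation peak anomalies, area-wide and per pixel."""

    region: str
    peak_months: tuple[int, ...]
    years: np.ndarray
    anomaly: np.ndarray
    pixel_anomaly: np.ndarray    # (n_years, n_pixels)
    pixel_mask: np.ndarray       # (rows, cols) bool

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.anomaly = np.asarray(self.anomaly, dtype=float)

    @property
    def n_years(self) -> int:
        return len(self.years)


# ---------------------------------------------------------------------------
# NDVI composites and peak anomalies
# ---------------------------------------------------------------------------

def monthly_max_composite(subm: ClimateCube) -> ClimateCube:
    """Monthly maxima of sub-monthly composites, bucketed by nominal start date."""
    labels = subm.time.labels
    keys: list[tuple[int, int]] = []
    for y, m, _ in labels:
        if not keys or keys[-1] != (y, m):
            keys.append((y, m))
    out = np.empty((len(keys),) + subm.grid.shape)
    valid = np.empty_like(out, dtype=bool)
    for i, (y, m) in enumerate(keys):
        idx = [j for j, (yy, mm, _) in enumerate(labels) if (yy, mm) == (y, m)]
        if not idx:
            raise ValueError(f"no composites in month {(y, m)}")
        vals = np.where(subm.valid_mask[idx], subm.values[idx], -np.inf)
        out[i] = vals.max(axis=0)
        valid[i] = subm.valid_mask[idx].any(axis=0)
    out = np.where(valid, out, np.nan)
    monthly = TimeAxis("monthly", tuple((y, m, 0) for y, m in keys))
    return ClimateCube(subm.product, subm.variable, subm.grid, monthly, out, valid)


def peak_anomaly(
    monthly_ndvi: ClimateCube,
    peak_months: tuple[int, ...],
    years: list[int] | np.ndarray,
    region: str = "region",
    pixel_mask: np.ndarray | None = None,
) -> NdviAnomalySeries:
    """Mean monthly-max NDVI over the peak months, centered per pixel and area-wide.

    The area series is the mean over valid pixels of the per-pixel peak value,
    centered on the across-year mean.  ``pixel_mask`` restricts the analyzed
    pixels (e.g. to vegetated classes).
    """
    years = np.asarray(years, dtype=int)
    T = len(years)
    peak = np.empty((T,) + monthly_ndvi.grid.shape)
    valid = np.ones(monthly_ndvi.grid.shape, dtype=bool)
    for i, y in enumerate(years):
        slices, ok = [], []
        for m in peak_months:
            try:
                t = monthly_ndvi.time.index_of(int(y), int(m))
            except KeyError:
                raise ValueError(f"peak month {(y, m)} missing from NDVI cube") from None
            slices.append(monthly_ndvi.values[t])
            ok.append(monthly_ndvi.valid_mask[t])
        peak[i] = np.mean(slices, axis=0)
        valid &= np.logical_and.reduce(ok)
    if pixel_mask is not None:
        valid &= pixel_mask
    if not valid.any():
        raise ValueError("no valid pixels for the peak-anomaly series")
    pix = peak[:, valid]                       # (T, n_pixels)
    pixel_anom = pix - pix.mean(axis=0, keepdims=True)
    area = pix.mean(axis=1)
    return NdviAnomalySeries(
        region=region, peak_months=tuple(int(m) for m in peak_months),
        years=years, anomaly=area - area.mean(),
        pixel_anomaly=pixel_anom, pixel_mask=valid,
    )


# ---------------------------------------------------------------------------
# Window aggregation and anomaly construction
# ---------------------------------------------------------------------------

def window_aggregate(
    monthly: ClimateCube, window: SeasonWindow, year: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean of the monthly values over the window's months for ``year``.

    Returns ``(values, valid)`` 2-D arrays.  Raises if a required month
    (including previous-year months) is not on the cube's axis.
    """
    slices, oks = [], []
    for off, m in window.months:
        try:
            t = monthly.time.index_of(year + off, m)
        except KeyError:
            raise ValueError(
                f"window {window.name!r} of {year} needs month {(year + off, m)} "
                "which is not on the cube's axis"
            ) from None
        slices.append(monthly.values[t])
        oks.append(monthly.valid_mask[t])
    valid = np.logical_and.reduce(oks)
    vals = np.where(valid, np.mean(slices, axis=0), np.nan)
    return vals, valid


def _aggregate_years(
    monthly: ClimateCube, window: SeasonWindow, years: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack window aggregates for all years (two-year averaging included).

    Returns ``(agg, valid, kept_years)``; years whose pre-period is missing
    for a two-year window are dropped from the front.
    """
    need_prev = window.two_year
    agg, valid, kept = [], [], []
    for y in years:
        try:
            v, ok = window_aggregate(monthly, window, int(y))
            if need_prev:
                vp, okp = window_aggregate(monthly, window, int(y) - 1)
                v, ok = (v + vp) / 2.0, ok & okp
        except ValueError:
            if not kept:          # leading years without data are dropped
                continue
            raise
        agg.append(v)
        valid.append(ok)
        kept.append(int(y))
    if not kept:
        raise ValueError(f"window {window.label!r} has no computable years")
    return np.array(agg), np.array(valid), np.array(kept)


def anomaly_series(
    monthly: ClimateCube,
    window: SeasonWindow,
    years: list[int] | np.ndarray,
    pixel_mask: np.ndarray | None = None,
    with_pixel: bool = True,
) -> FeatureSeries:
    """Build a mean-zero :class:`FeatureSeries` from a monthly cube.

    A year whose area aggregate touches an invalid value (a pixel invalid in
    that year but valid in others) is dropped from the feature with a logged
    warning; pixels invalid in every year are excluded outright.
    """
    years = np.asarray(years, dtype=int)
    if len(years) < 3:
        raise ValueError("need at least 3 years for an anomaly series")
    agg, valid, kept = _aggregate_years(monthly, window, years)
    if pixel_mask is not None:
        valid = valid & pixel_mask[None, :, :]
    base = valid.any(axis=0)
    if not base.any():
        raise ValueError(f"no valid pixels for feature window {window.label!r}")
    year_ok = valid[:, base].all(axis=1)
    dropped = tuple(int(y) for y in np.concatenate(
        [np.setdiff1d(years, kept), kept[~year_ok]]))
    if dropped:
        logger.warning("feature %s/%s: dropped years %s (incomplete data)",
                       monthly.product, window.label, dropped)
    kept = kept[year_ok]
    if len(kept) < 3:
        raise ValueError("fewer than 3 usable years after dropping incomplete ones")
    if np.any(np.diff(kept) != 1):
        raise ValueError("usable years are not contiguous")
    pix = agg[year_ok][:, base]
    area = pix.mean(axis=1)
    fs = FeatureSeries(
        product=monthly.product, variable=monthly.variable, window=window,
        years=kept, anomaly=area - area.mean(),
        pixel_anomaly=(pix - pix.mean(axis=0, keepdims=True)) if with_pixel else None,
        pixel_mask=base if with_pixel else None,
        dropped_years=dropped,
    )
    return fs


def standardize(series: FeatureSeries | NdviAnomalySeries):
    """Divide the anomaly by its across-year SD (ddof=1); unit variance."""
    sd = float(np.std(series.anomaly, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant series")
    import copy

    out = copy.copy(series)
    out.anomaly = series.anomaly / sd
    if getattr(series, "pixel_anomaly", None) is not None:
        out.pixel_anomaly = series.pixel_anomaly / sd
    return out


# ---------------------------------------------------------------------------
# Feature catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDescriptor:
    product: str
    variable: str
    window: SeasonWindow

    @property
    def feature_id(self) -> str:
        return f"{self.product}:{self.variable}/{self.window.label}"


def build_feature_catalog(
    products: list[tuple[str, list[str]]],
    windows: tuple[SeasonWindow, ...] = DEFAULT_WINDOWS,
    snow_variables: frozenset[str] = SNOW_VARIABLES,
    snow_excluded_windows: frozenset[str] = SNOW_EXCLUDED_WINDOWS,
    include_two_year: bool = True,
) -> list[FeatureDescriptor]:
    """Cross product of variables x windows (and two-year variants).

    Snow variables are never paired with windows in ``snow_excluded_windows``
    (the summer-containing windows).  Raises on duplicate feature ids.
    """
    catalog: list[FeatureDescriptor] = []
    for product, variables in products:
        for var in variables:
            for win in windows:
                if var in snow_variables and win.name in snow_excluded_windows:
                    continue
                catalog.append(FeatureDescriptor(product, var, win))
                if include_two_year:
                    catalog.append(FeatureDescriptor(product, var, win.as_two_year()))
    ids = [d.feature_id for d in catalog]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature identifiers in catalog")
    logger.info("feature catalog: %d features", len(catalog))
    return catalog


def compute_features(
    monthly_cubes: dict[tuple[str, str], ClimateCube],
    catalog: list[FeatureDescriptor],
    years: list[int] | np.ndarray,
    pixel_mask: np.ndarray | None = None,
    with_pixel: bool = True,
) -> list[FeatureSeries]:
    """Materialize every catalog entry from its (product, variable) cube."""
    out = []
    for desc in catalog:
        cube = monthly_cubes[(desc.product, desc.variable)]
        out.append(anomaly_series(cube, desc.window, years, pixel_mask, with_pixel))
    return out
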