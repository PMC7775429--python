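"""Daily snow-index processing: exclusion, gap-filling, FSC, SCD, monthly means.

The daily input is a gappy NDSI cube on the MOD10A1-style integer scale
0-100.  Processing follows the standard recipe for such products: pixels with
too many invalid days over the whole series are dropped, remaining gaps are
filled by linear interpolation in time (edges copy the nearest observation),
fractional snow cover is the linear NDSI transform ``FSC = -0.01 + 1.45 * NDSI``
truncated to [0, 100] %, and snow-cover duration counts days with NDSI
strictly above the threshold (0.2 on the 0-1 scale, i.e. 20 on the 0-100
scale used here; both the scale and threshold are configurable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .cubes import ClimateCube, TimeAxis

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnowConfig:
    """Tunables of the snow pipeline (defaults follow the 0-100 NDSI scale)."""

    missing_exclusion_fraction: float = 0.60
    scd_ndsi_threshold: float = 20.0
    fsc_slope: float = 1.45
    fsc_intercept: float = -0.01
    fsc_bounds: tuple[float, float] = (0.0, 100.0)
    ndsi_scale: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.missing_exclusion_fraction < 1:
            raise ValueError("missing_exclusion_fraction must be in (0, 1)")
        if not self.fsc_bounds[0] < self.fsc_bounds[1]:
            raise ValueError("fsc_bounds must be increasing")


def exclude_high_missing(
    daily: ClimateCube, cfg: SnowConfig = SnowConfig()
) -> tuple[ClimateCube, float]:
    """Drop pixels whose invalid-day fraction strictly exceeds the threshold.

    Returns the cube (excluded pixels invalid at all times) and the areal
    fraction of pixels excluded.  A pixel at exactly the threshold is kept.
    """
    if len(daily.time) == 0:
        raise ValueError("empty time axis")
    invalid_frac = 1.0 - daily.valid_mask.mean(axis=0)
    excluded = invalid_frac > cfg.missing_exclusion_fraction
    valid = daily.valid_mask & ~excluded[None, :, :]
    values = np.where(valid, daily.values, np.nan)
    frac = float(excluded.mean())
    logger.info("excluded %.1f%% of pixels (>%d%% invalid days)",
                100 * frac, round(100 * cfg.missing_exclusion_fraction))
    return daily.with_values(values, valid), frac


def _fill_series(series: np.ndarray, valid: np.ndarray) -> np.ndarray:
    idx = np.flatnonzero(valid)
    # np.interp holds the nearest observed value beyond both ends, which is
    # exactly the closest-available-value edge rule.
    return np.interp(np.arange(series.size), idx, series[idx])


def gap_fill_linear(daily: ClimateCube, on_empty: str = "skip") -> ClimateCube:
    """Fill gaps per pixel, linear in day index; edges copy nearest value.

    Observed values are unchanged.  Pixels with zero valid observations
    (typically those removed by :func:`exclude_high_missing`) stay invalid
    when ``on_empty="skip"``; ``on_empty="raise"`` makes them an error.
    """
    T = len(daily.time)
    values = daily.values.reshape(T, -1).copy()
    valid = daily.valid_mask.reshape(T, -1)
    n_valid = valid.sum(axis=0)
    empty = n_valid == 0
    if empty.any() and on_empty == "raise":
        raise ValueError(f"{int(empty.sum())} retained pixels have no valid observation")
    out_valid = np.ones_like(valid)
    out_valid[:, empty] = False
    need = np.flatnonzero((n_valid < T) & ~empty)
    for j in need:
        values[:, j] = _fill_series(values[:, j], valid[:, j])
    values[:, empty] = np.nan
    shape = daily.values.shape
    return daily.with_values(values.reshape(shape), out_valid.reshape(shape))


def fsc_from_ndsi(ndsi_cube: ClimateCube, cfg: SnowConfig = SnowConfig()) -> ClimateCube:
    """Linear NDSI -> fractional snow cover (%), truncated to the bounds."""
    raw = cfg.fsc_intercept + cfg.fsc_slope * ndsi_cube.values
    fsc = np.clip(raw, cfg.fsc_bounds[0], cfg.fsc_bounds[1])
    fsc = np.where(ndsi_cube.valid_mask, fsc, np.nan)
    return ClimateCube(ndsi_cube.product, "fsc", ndsi_cube.grid, ndsi_cube.time,
                       fsc, ndsi_cube.valid_mask.copy())


def _month_groups(time: TimeAxis) -> tuple[TimeAxis, list[np.ndarray]]:
    """Group a daily axis by calendar month, preserving order."""
    ym = [(y, m) for y, m, _ in time.labels]
    keys: list[tuple[int, int]] = []
    for k in ym:
        if not keys or keys[-1] != k:
            keys.append(k)
    groups = [np.array([i for i, k in enumerate(ym) if k == key]) for key in keys]
    monthly = TimeAxis("monthly", tuple((y, m, 0) for y, m in keys))
    return monthly, groups


def scd(
    daily_ndsi: ClimateCube,
    cfg: SnowConfig = SnowConfig(),
    grouping: TimeAxis | None = None,
) -> ClimateCube:
    """Monthly snow-cover duration: days with NDSI strictly above threshold.

    Operates on the gap-filled cube; pixels without valid data stay invalid.
    ``grouping`` may pin the expected monthly axis (checked for consistency).
    """
    monthly, groups = _month_groups(daily_ndsi.time)
    if grouping is not None and grouping.labels != monthly.labels:
        raise ValueError("grouping axis does not match the daily cube's months")
    above = (daily_ndsi.values > cfg.scd_ndsi_threshold) & daily_ndsi.valid_mask
    any_valid = daily_ndsi.valid_mask
    counts = np.empty((len(monthly),) + daily_ndsi.grid.shape)
    valid = np.empty_like(counts, dtype=bool)
    for i, g in enumerate(groups):
        counts[i] = above[g].sum(axis=0)
        valid[i] = any_valid[g].all(axis=0)
    counts = np.where(valid, counts, np.nan)
    return ClimateCube(daily_ndsi.product, "scd", daily_ndsi.grid, monthly, counts, valid)


def monthly_aggregate(daily: ClimateCube, stat: str = "mean") -> ClimateCube:
    """Aggregate a daily cube to one slice per calendar month (mean)."""
    if stat != "mean":
        raise ValueError("only the mean statistic is supported")
    monthly, groups = _month_groups(daily.time)
    if any(len(g) == 0 for g in groups):
        raise ValueError("month with zero days on the axis")
    out = np.empty((len(monthly),) + daily.grid.shape)
    valid = np.empty_like(out, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, g in enumerate(groups):
            valid[i] = daily.valid_mask[g].all(axis=0)
            out[i] = np.where(valid[i], daily.values[g].mean(axis=0), np.nan)
    return ClimateCube(daily.product, daily.variable, daily.grid, monthly, out, valid)


def snow_monthly_metrics(
    daily_ndsi: ClimateCube, cfg: SnowConfig = SnowConfig()
) -> dict[str, ClimateCube]:
    """Full daily->monthly snow pipeline: returns ndsi, fsc and scd cubes."""
    retained, frac = exclude_high_missing(daily_ndsi, cfg)
    filled = gap_fill_linear(retained)
    fsc_daily = fsc_from_ndsi(filled, cfg)
    return {
        "ndsi": monthly_aggregate(filled),
        "fsc": monthly_aggregate(fsc_daily),
        "scd": scd(filled, cfg),
    }
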