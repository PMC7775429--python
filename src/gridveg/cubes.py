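"""Grid/time data model shared by every pipeline stage.

A :class:`ClimateCube` holds one variable of one product as a dense
``(time, row, col)`` array with an explicit validity mask.  All products are
assumed pre-projected to one common CRS; the artifact validates grid
compatibility but performs no projection math (the CRS is an opaque label).

Pixel convention: 0-based (row, col); the grid origin is the outer corner of
pixel (0, 0); pixel centers sit at ``origin + (index + 0.5) * cell_size`` with
both axes increasing with the index.  Nearest-neighbor regridding assigns each
target pixel the value of the source cell whose half-open interval
``[edge, edge)`` contains the target pixel center, so ties are impossible and
no value blending ever occurs.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Vegetation classes of the study regions, in storage order.
VEGETATION_CLASSES = ("riparian", "dwarf_shrub_steppe", "alpine_grassland", "non_vegetated")
VEGETATED_CLASSES = frozenset(VEGETATION_CLASSES[:3])

RESOLUTIONS = ("daily", "sixteen_day", "monthly", "annual")

#: Nominal start day-of-year of the 23 sixteen-day composites per year.
SIXTEEN_DAY_DOYS = tuple(range(1, 366, 16))


class GridError(ValueError):
    """Raised for invalid or incompatible grid specifications."""


class TimeAxisError(ValueError):
    """Raised for malformed time axes."""


@dataclass(frozen=True)
class GridSpec:
    """Regular raster grid: shape, cell size and origin of pixel (0, 0)."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_label: str = ""

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise GridError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates ``(ys, xs)`` along each axis."""
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        return ys, xs

    def extent(self) -> tuple[float, float, float, float]:
        """``(x_min, x_max, y_min, y_max)`` outer bounds of the grid."""
        return (
            self.origin_x,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
            self.origin_y + self.n_rows * self.cell_size,
        )


def _month_add(year: int, month: int, k: int) -> tuple[int, int]:
    m = (month - 1 + k) % 12 + 1
    y = year + (month - 1 + k) // 12
    return y, m


@dataclass(frozen=True)
class TimeAxis:
    """Ordered, gap-free time labels at one of the supported resolutions.

    Labels are ``(year, month, day)`` tuples; ``month``/``day`` are 0 where
    the resolution does not use them (annual/monthly).  For the sixteen-day
    resolution the labels are the nominal composite start dates of the
    standard 23-composites-per-year schedule.
    """

    resolution: str
    labels: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTIONS:
            raise TimeAxisError(f"unknown resolution {self.resolution!r}")
        if len(self.labels) == 0:
            raise TimeAxisError("empty time axis")
        self._check_gap_free()

    def _check_gap_free(self) -> None:
        labs = self.labels
        if self.resolution == "annual":
            years = [y for y, _, _ in labs]
            if years != list(range(years[0], years[0] + len(years))):
                raise TimeAxisError("annual axis must be consecutive years")
        elif self.resolution == "monthly":
            y0, m0, _ = labs[0]
            for k, (y, m, _) in enumerate(labs):
                if (y, m) != _month_add(y0, m0, k):
                    raise TimeAxisError("monthly axis must be consecutive months")
        elif self.resolution == "daily":
            d0 = _dt.date(*labs[0])
            for k, (y, m, d) in enumerate(labs):
                if _dt.date(y, m, d) != d0 + _dt.timedelta(days=k):
                    raise TimeAxisError("daily axis must be consecutive days")
        else:  # sixteen_day: follow the nominal DOY schedule
            prev = None
            for y, m, d in labs:
                doy = (_dt.date(y, m, d) - _dt.date(y, 1, 1)).days + 1
                if doy not in SIXTEEN_DAY_DOYS:
                    raise TimeAxisError(f"{(y, m, d)} is not a nominal composite start")
                idx = SIXTEEN_DAY_DOYS.index(doy)
                if prev is not None:
                    py, pidx = prev
                    ny, nidx = (py, pidx + 1) if pidx + 1 < len(SIXTEEN_DAY_DOYS) else (py + 1, 0)
                    if (y, idx) != (ny, nidx):
                        raise TimeAxisError("sixteen_day axis has gaps")
                prev = (y, idx)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def years(self) -> np.ndarray:
        return np.array([y for y, _, _ in self.labels])

    @property
    def months(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.labels])

    def index_of(self, year: int, month: int | None = None) -> int:
        for i, (y, m, _) in enumerate(self.labels):
            if y == year and (month is None or m == month):
                return i
        raise KeyError(f"({year}, {month}) not on axis")

    def to_datetimes(self) -> np.ndarray:
        """datetime64 representation (first day for monthly/annual labels)."""
        out = []
        for y, m, d in self.labels:
            out.append(np.datetime64(f"{y:04d}-{max(m, 1):02d}-{max(d, 1):02d}"))
        return np.array(out)

    # -- constructors ------------------------------------------------------

    @classmethod
    def monthly(cls, start_year: int, start_month: int, n_months: int) -> "TimeAxis":
        labs = tuple((*_month_add(start_year, start_month, k), 0) for k in range(n_months))
        return cls("monthly", labs)

    @classmethod
    def daily(cls, start: _dt.date, n_days: int) -> "TimeAxis":
        labs = tuple(
            ((start + _dt.timedelta(days=k)).year,
             (start + _dt.timedelta(days=k)).month,
             (start + _dt.timedelta(days=k)).day)
            for k in range(n_days)
        )
        return cls("daily", labs)

    @classmethod
    def daily_years(cls, first_year: int, n_years: int) -> "TimeAxis":
        start = _dt.date(first_year, 1, 1)
        end = _dt.date(first_year + n_years - 1, 12, 31)
        return cls.daily(start, (end - start).days + 1)

    @classmethod
    def sixteen_day(cls, first_year: int, n_years: int) -> "TimeAxis":
        labs = []
        for y in range(first_year, first_year + n_years):
            for doy in SIXTEEN_DAY_DOYS:
                date = _dt.date(y, 1, 1) + _dt.timedelta(days=doy - 1)
                labs.append((date.year, date.month, date.day))
        return cls("sixteen_day", tuple(labs))

    @classmethod
    def annual(cls, first_year: int, n_years: int) -> "TimeAxis":
        return cls("annual", tuple((first_year + k, 0, 0) for k in range(n_years)))


@dataclass
class ClimateCube:
    """One variable of one product: values + validity on a grid x time axis."""

    product: str
    variable: str
    grid: GridSpec
    time: TimeAxis
    values: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.time), self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected:
            raise GridError(f"values shape {self.values.shape} != grid x time {expected}")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != expected:
                raise GridError("valid_mask shape mismatch")
            self.valid_mask &= np.isfinite(self.values)
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise GridError("non-finite values marked valid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "ClimateCube":
        return ClimateCube(
            self.product, self.variable, self.grid, self.time,
            self.values.copy(), self.valid_mask.copy(),
        )

    def with_values(self, values: np.ndarray, valid_mask: np.ndarray | None = None) -> "ClimateCube":
        return ClimateCube(self.product, self.variable, self.grid, self.time,
                           values, valid_mask)


@dataclass
class ClassRaster:
    """Categorical vegetation-class raster on the NDVI grid."""

    grid: GridSpec
    class_id: np.ndarray  # int indices into VEGETATION_CLASSES

    def __post_init__(self) -> None:
        self.class_id = np.asarray(self.class_id)
        if self.class_id.shape != self.grid.shape:
            raise GridError("class raster shape mismatch")
        if self.class_id.min() < 0 or self.class_id.max() >= len(VEGETATION_CLASSES):
            raise GridError("class ids out of range")

    def mask_for(self, classes: set[str] | frozenset[str]) -> np.ndarray:
        """Boolean pixel mask: True where the pixel class is in ``classes``."""
        ids = [i for i, name in enumerate(VEGETATION_CLASSES) if name in classes]
        return np.isin(self.class_id, ids)

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.class_id == i))
            for i, name in enumerate(VEGETATION_CLASSES)
        }


# ---------------------------------------------------------------------------
# Regridding and masking
# ---------------------------------------------------------------------------

def nearest_source_indices(source: GridSpec, target: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map each target pixel center to its enclosing source cell.

    Returns ``(rows, cols, inside)`` where ``rows``/``cols`` index the source
    grid per target pixel and ``inside`` flags target centers that fall within
    the source extent.
    """
    tys, txs = target.pixel_centers()
    rows_f = np.floor((tys - source.origin_y) / source.cell_size).astype(int)
    cols_f = np.floor((txs - source.origin_x) / source.cell_size).astype(int)
    in_rows = (rows_f >= 0) & (rows_f < source.n_rows)
    in_cols = (cols_f >= 0) & (cols_f < source.n_cols)
    inside = in_rows[:, None] & in_cols[None, :]
    rows = np.clip(rows_f, 0, source.n_rows - 1)
    cols = np.clip(cols_f, 0, source.n_cols - 1)
    return rows, cols, inside


def regrid_nearest(cube: ClimateCube, target: GridSpec) -> ClimateCube:
    """Nearest-neighbor regrid onto ``target``; values are never blended.

    Every output value equals exactly one input cell's value; validity is
    propagated from the source cell.  Target pixels whose centers fall outside
    the source extent are invalid.  Raises :class:`GridError` if no target
    pixel center lies inside the source extent (disjoint grids).
    """
    if cube.grid == target:
        return cube.copy()
    rows, cols, inside = nearest_source_indices(cube.grid, target)
    if not inside.any():
        raise GridError("source and target grids are spatially disjoint")
    values = cube.values[:, rows[:, None], cols[None, :]]
    valid = cube.valid_mask[:, rows[:, None], cols[None, :]] & inside[None, :, :]
    values = np.where(valid, values, np.nan)
    return ClimateCube(cube.product, cube.variable, target, cube.time, values, valid)


def apply_class_mask(
    cube: ClimateCube, classes: ClassRaster, keep: set[str] | frozenset[str]
) -> tuple[ClimateCube, int]:
    """Invalidate pixels outside ``keep`` at every time step.

    Returns the masked cube and the number of pixels retained by the class
    mask (irrespective of per-time validity).  Idempotent.
    """
    if cube.grid != classes.grid:
        raise GridError("cube grid does not match class raster grid")
    pixel_keep = classes.mask_for(keep)
    valid = cube.valid_mask & pixel_keep[None, :, :]
    values = np.where(valid, cube.values, np.nan)
    n_kept = int(pixel_keep.sum())
    logger.info("class mask kept %d of %d pixels", n_kept, classes.grid.n_pixels)
    return ClimateCube(cube.product, cube.variable, cube.grid, cube.time, values, valid), n_kept


def subset_years(cube: ClimateCube, first_year: int, last_year: int) -> ClimateCube:
    """Restrict a cube to labels with ``first_year <= year <= last_year``."""
    sel = (cube.time.years >= first_year) & (cube.time.years <= last_year)
    labels = tuple(lab for lab, s in zip(cube.time.labels, sel) if s)
    axis = TimeAxis(cube.time.resolution, labels)
    return ClimateCube(cube.product, cube.variable, cube.grid, axis,
                       cube.values[sel], cube.valid_mask[sel])
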