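"""Rectilinear grid geometry and daily gridded fields.

The analysis domain is a rectilinear latitude/longitude grid of square
(in degrees) cells, 0.03 deg by default, indexed ``[i, j]`` with ``i``
increasing northward and ``j`` increasing eastward.  Cell membership is
half-open: a point belongs to cell ``i`` when
``center_i - cell/2 <= coord < center_i + cell/2``, so no point is ever
counted twice.  Distances are great-circle (haversine) on a sphere of
radius 6371.0088 km.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class GridSpec:
    """A rectilinear grid of cell centers.

    Parameters
    ----------
    lat0, lon0 : float
        Southern-most and western-most cell *centers*, decimal degrees.
    n_lat, n_lon : int
        Number of rows (latitude) and columns (longitude); both >= 2.
    cell : float
        Cell size in degrees (same in both directions), > 0.
    """

    lat0: float
    lon0: float
    n_lat: int
    n_lon: int
    cell: float = 0.03

    def __post_init__(self):
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.n_lat < 2 or self.n_lon < 2:
            raise ValueError("grid must be at least 2x2")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.cell * np.arange(self.n_lat)

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.cell * np.arange(self.n_lon)

    def cell_index(self, lat, lon):
        """Map coordinates to integer cell indices (half-open membership).

        Returns ``(i, j)`` arrays; points outside the grid get -1.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.floor((lat - (self.lat0 - self.cell / 2.0)) / self.cell).astype(int)
        j = np.floor((lon - (self.lon0 - self.cell / 2.0)) / self.cell).astype(int)
        bad = (i < 0) | (i >= self.n_lat) | (j < 0) | (j >= self.n_lon)
        i = np.where(bad, -1, i)
        j = np.where(bad, -1, j)
        return i, j

    def cell_area_km2(self) -> np.ndarray:
        """Spherical-patch area of each row's cells, shape (n_lat, 1).

        A = R^2 * dlon_rad * (sin(lat_top) - sin(lat_bot)).
        """
        half = self.cell / 2.0
        top = np.radians(self.lats + half)
        bot = np.radians(self.lats - half)
        dlon = np.radians(self.cell)
        area = EARTH_RADIUS_KM**2 * dlon * (np.sin(top) - np.sin(bot))
        return area[:, None] * np.ones((1, self.n_lon))

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D arrays of cell-center (lat, lon), shape (n_lat, n_lon)."""
        return np.meshgrid(self.lats, self.lons, indexing="ij")


@dataclass
class DailyField:
    """One day of one gridded variable with an explicit missingness mask.

    ``mask`` is True where the value is missing; ``values`` must be finite
    wherever the mask is False.
    """

    grid: GridSpec
    date: Date
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite values present outside the missingness mask")

    @property
    def filled_nan(self) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = np.nan
        return out


class FieldStack:
    """A (time, lat, lon) stack of one variable on a fixed grid.

    Thin container used throughout the pipeline; ``stack[i]`` or
    ``stack.at(date)`` return :class:`DailyField` views.
    """

    def __init__(self, grid: GridSpec, dates: Sequence[Date], values: np.ndarray, mask: np.ndarray | None = None):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(dates), grid.n_lat, grid.n_lon):
            raise ValueError("values shape does not match (n_dates, n_lat, n_lon)")
        if mask is None:
            mask = ~np.isfinite(values)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask shape mismatch")
        self.grid = grid
        self.dates = list(dates)
        self.values = values
        self.mask = mask
        self._date_index = {d: i for i, d in enumerate(self.dates)}

    def __len__(self) -> int:
        return len(self.dates)

    def __getitem__(self, i: int) -> DailyField:
        return DailyField(self.grid, self.dates[i], self.values[i], self.mask[i])

    def at(self, date: Date) -> DailyField:
        return self[self._date_index[date]]

    def has(self, date: Date) -> bool:
        return date in self._date_index

    @property
    def filled_nan(self) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def copy(self) -> "FieldStack":
        return FieldStack(self.grid, self.dates, self.values.copy(), self.mask.copy())

    @classmethod
    def from_fields(cls, fields: Iterable[DailyField]) -> "FieldStack":
        fields = list(fields)
        if not fields:
            raise ValueError("empty field list")
        grid = fields[0].grid
        return cls(grid, [f.date for f in fields], np.stack([f.values for f in fields]), np.stack([f.mask for f in fields]))


# IMD season labels used for gap seasonality and seasonal mean maps.
SEASON_OF_MONTH = {
    1: "winter", 2: "winter",
    3: "pre-monsoon", 4: "pre-monsoon", 5: "pre-monsoon",
    6: "monsoon", 7: "monsoon", 8: "monsoon", 9: "monsoon",
    10: "post-monsoon", 11: "post-monsoon", 12: "post-monsoon",
}

SEASONS = ("winter", "pre-monsoon", "monsoon", "post-monsoon")


def season_of(date: Date) -> str:
    return SEASON_OF_MONTH[date.month]
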