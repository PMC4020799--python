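"""Analysis lattice for overlaying tracking locations and environmental data.

The study region is gridded into square cells of ``cell_deg`` degrees
(0.04 degrees, roughly 4 km^2 at these latitudes, by default).  Cells are
indexed row-major from the north-west corner: cell ``(r, c)`` covers the
half-open box

    lon in [lon_min + c*cell, lon_min + (c+1)*cell)
    lat in (lat_max - (r+1)*cell, lat_max - r*cell]

so every point of the region maps to at most one cell, and a point lying
exactly on an interior edge belongs to the cell for which that coordinate
is the half-open boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "DEFAULT_BOUNDS", "DEFAULT_CELL_DEG", "make_grid"]

#: Geographic limits of the tracking data: 10W-110W, 40S-75S.
DEFAULT_BOUNDS = (-110.0, -10.0, -75.0, -40.0)
DEFAULT_CELL_DEG = 0.04

# Tolerance (in cell units) used to snap points that sit numerically on a
# cell edge onto the edge before applying the half-open convention.
_EDGE_SNAP = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic lattice in WGS84 lon/lat degrees."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_deg: float
    n_cols: int = field(init=False)
    n_rows: int = field(init=False)

    def __post_init__(self) -> None:
        if self.cell_deg <= 0:
            raise ValueError(f"cell_deg must be positive, got {self.cell_deg}")
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError(
                "inverted bounds: require lon_min < lon_max and lat_min < lat_max"
            )
        object.__setattr__(
            self, "n_cols", int(round((self.lon_max - self.lon_min) / self.cell_deg))
        )
        object.__setattr__(
            self, "n_rows", int(round((self.lat_max - self.lat_min) / self.cell_deg))
        )
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must contain at least one cell per axis")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, west to east (column order)."""
        c = np.arange(self.n_cols)
        return self.lon_min + (c + 0.5) * self.cell_deg

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (row order)."""
        r = np.arange(self.n_rows)
        return self.lat_max - (r + 0.5) * self.cell_deg

    def point_to_cell(self, lon, lat):
        """Map lon/lat points to (row, col); (-1, -1) for points off the grid.

        Vectorized; honors the half-open convention with an epsilon snap so
        points sitting on an edge up to floating-point noise land on the
        cell the convention assigns.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # In fractional-cell units both axes become half-open [k, k+1):
        # row r holds v = (lat_max - lat)/cell in [r, r+1) (the closed top
        # edge lat_max - r*cell maps to v == r exactly).
        u = (lon - self.lon_min) / self.cell_deg
        v = (self.lat_max - lat) / self.cell_deg

        u_snap = np.round(u)
        u = np.where(np.abs(u - u_snap) < _EDGE_SNAP, u_snap, u)
        v_snap = np.round(v)
        v = np.where(np.abs(v - v_snap) < _EDGE_SNAP, v_snap, v)

        col = np.floor(u).astype(int)
        row = np.floor(v).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def cell_id(self, row, col):
        """Row-major scalar id; -1 propagates for off-grid points."""
        row = np.asarray(row)
        col = np.asarray(col)
        cid = row * self.n_cols + col
        return np.where((row < 0) | (col < 0), -1, cid)

    def id_to_rowcol(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_center(self, cell_id):
        """Lon/lat center of cells given by scalar id."""
        r, c = self.id_to_rowcol(cell_id)
        lon = self.lon_min + (np.asarray(c) + 0.5) * self.cell_deg
        lat = self.lat_max - (np.asarray(r) + 0.5) * self.cell_deg
        return lon, lat

    def contains(self, lon, lat) -> np.ndarray:
        r, _ = self.point_to_cell(lon, lat)
        return np.asarray(r) >= 0


def make_grid(
    bounds: tuple[float, float, float, float] = DEFAULT_BOUNDS,
    cell_deg: float = DEFAULT_CELL_DEG,
) -> GridSpec:
    """Build the analysis lattice from ``(lon_min, lon_max, lat_min, lat_max)``.

    With the default bounds and 0.04-degree cells this yields the study
    lattice of 875 rows x 2500 columns.
    """
    lon_min, lon_max, lat_min, lat_max = bounds
    return GridSpec(lon_min, lon_max, lat_min, lat_max, cell_deg)
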