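"""Environmental layers on the analysis lattice.

Candidate covariates for habitat modelling are bathymetry (BAT, m),
chlorophyll-a concentration (CHLa, mg m-3), sea-surface temperature
(SST, degC) and sea-surface height (SSH, cm), each paired with a local
"proportional change" gradient (BAT.G3, CHLa.G3, SST.G3, SSH.G3, in %)
computed over a 3x3 moving window.  Monthly fields are composited over the
modelling window, gradients are taken on the raw values, and everything is
standardized (zero mean, unit sd) before entering the GLMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage, stats

from .grid import GridSpec

__all__ = [
    "CANONICAL_VARIABLES",
    "EnvLayer",
    "EnvStack",
    "aggregate_to_grid",
    "gradient_pc",
    "temporal_composite",
    "standardize",
    "spearman_screen",
    "canonical_name",
]

#: The eight candidate covariates, in canonical (lexicographic-stable) order.
CANONICAL_VARIABLES = (
    "BAT",
    "BAT.G3",
    "CHLA",
    "CHLA.G3",
    "SSH",
    "SSH.G3",
    "SST",
    "SST.G3",
)

_ALIASES = {v.upper(): v for v in CANONICAL_VARIABLES}
_ALIASES.update({"CHLA": "CHLA", "CHLA.G3": "CHLA.G3"})


def canonical_name(name: str) -> str:
    """Normalize a covariate code; mixed-case aliases like ``CHLa`` accepted."""
    key = name.strip().upper()
    if key not in _ALIASES:
        raise KeyError(f"unknown environmental variable {name!r}")
    return _ALIASES[key]


@dataclass
class EnvLayer:
    """One gridded variable for one month (or a multi-month composite).

    ``values`` is a float array of shape ``grid.shape``; missing cells are
    NaN.
    """

    variable_name: str
    values: np.ndarray
    month: str = "composite"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("layer values must be 2-D (rows x cols)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class EnvStack:
    """Named layers sharing one grid, with standardization bookkeeping."""

    grid: GridSpec
    layers: dict[str, EnvLayer] = field(default_factory=dict)
    #: variable -> (mean, sd) recorded by :func:`standardize`; empty until then.
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def add(self, layer: EnvLayer) -> None:
        if layer.shape != self.grid.shape:
            raise ValueError(
                f"layer {layer.variable_name!r} shape {layer.shape} does not "
                f"match grid {self.grid.shape}"
            )
        self.layers[canonical_name(layer.variable_name)] = layer

    def __contains__(self, name: str) -> bool:
        return canonical_name(name) in self.layers

    def __getitem__(self, name: str) -> EnvLayer:
        return self.layers[canonical_name(name)]

    @property
    def variable_names(self) -> list[str]:
        return sorted(self.layers)

    def complete_cells(self, variables=None) -> np.ndarray:
        """Scalar ids of cells with non-missing data for every variable."""
        names = self.variable_names if variables is None else [
            canonical_name(v) for v in variables
        ]
        ok = np.ones(self.grid.shape, dtype=bool)
        for name in names:
            ok &= np.isfinite(self.layers[name].values)
        return np.flatnonzero(ok.ravel())

    def design_matrix(self, cell_ids, variables) -> np.ndarray:
        """(n_cells, n_vars) matrix of layer values at the given cells."""
        cell_ids = np.asarray(cell_ids)
        cols = [
            self.layers[canonical_name(v)].values.ravel()[cell_ids]
            for v in variables
        ]
        return np.column_stack(cols) if cols else np.empty((len(cell_ids), 0))

    # ---------------------------------------------------------- persistence
    def to_dataset(self) -> xr.Dataset:
        g = self.grid
        ds = xr.Dataset(
            {
                name: (("lat", "lon"), layer.values)
                for name, layer in self.layers.items()
            },
            coords={"lon": g.lon_centers(), "lat": g.lat_centers()},
            attrs={
                "lon_min": g.lon_min,
                "lon_max": g.lon_max,
                "lat_min": g.lat_min,
                "lat_max": g.lat_max,
                "cell_deg": g.cell_deg,
                "crs": "EPSG:4326",
            },
        )
        for name, (mu, sd) in self.standardization.items():
            ds[name].attrs.update({"standardized_mean": mu, "standardized_sd": sd})
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path)

    @classmethod
    def from_netcdf(cls, path) -> "EnvStack":
        with xr.open_dataset(path) as ds:
            ds = ds.load()
        a = ds.attrs
        grid = GridSpec(a["lon_min"], a["lon_max"], a["lat_min"], a["lat_max"],
                        a["cell_deg"])
        stack = cls(grid)
        for name in ds.data_vars:
            stack.add(EnvLayer(str(name), ds[name].values))
            va = ds[name].attrs
            if "standardized_mean" in va:
                stack.standardization[canonical_name(str(name))] = (
                    float(va["standardized_mean"]),
                    float(va["standardized_sd"]),
                )
        return stack


def aggregate_to_grid(raster: xr.DataArray, grid: GridSpec,
                      variable_name: str | None = None,
                      month: str = "composite") -> EnvLayer:
    """Average a finer georeferenced raster onto the analysis lattice.

    ``raster`` must carry 1-D ``lon`` and ``lat`` coordinates giving pixel
    centers.  Each grid cell takes the mean of the source pixels whose
    centers fall inside it; a cell covered by no pixel (or only missing
    pixels) is missing.
    """
    if "lon" not in raster.coords or "lat" not in raster.coords:
        raise ValueError("raster needs 1-D 'lon' and 'lat' center coordinates")
    lon = raster["lon"].values
    lat = raster["lat"].values
    vals = raster.transpose("lat", "lon").values.astype(float)

    lon2, lat2 = np.meshgrid(lon, lat)
    row, col = grid.point_to_cell(lon2.ravel(), lat2.ravel())
    inside = row >= 0
    if not inside.any():
        raise ValueError("raster lies wholly outside the grid")
    v = vals.ravel()[inside]
    cid = (row[inside] * grid.n_cols + col[inside])

    finite = np.isfinite(v)
    sums = np.bincount(cid[finite], weights=v[finite], minlength=grid.n_cells)
    counts = np.bincount(cid[finite], minlength=grid.n_cells)
    out = np.full(grid.n_cells, np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    name = variable_name or str(raster.name or "layer")
    return EnvLayer(name, out.reshape(grid.shape), month=month)


def gradient_pc(layer: EnvLayer, out_name: str | None = None) -> EnvLayer:
    """Proportional-change gradient over a 3x3 moving window.

    For each cell, PC = (max - min) * 100 / max over the 3x3 neighborhood
    (window truncated at the grid edge; missing neighbors ignored).  A flat
    neighborhood gives 0, and an all-zero neighborhood gives 0 by
    convention.  Values must be non-negative — shift or transform the layer
    first otherwise — so the result always lies in [0, 100].
    """
    x = layer.values
    if np.nanmin(x) < 0:
        raise ValueError(
            f"gradient_pc requires non-negative values; {layer.variable_name} "
            "has negatives — shift or transform the layer first"
        )
    valid = np.isfinite(x)
    hi = ndimage.maximum_filter(np.where(valid, x, -np.inf), size=3,
                                mode="constant", cval=-np.inf)
    lo = ndimage.minimum_filter(np.where(valid, x, np.inf), size=3,
                                mode="constant", cval=np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = np.where(hi > 0, (hi - lo) * 100.0 / hi, 0.0)
    pc = np.where(valid, pc, np.nan)  # gradient undefined where the cell is
    name = out_name or f"{layer.variable_name}.G3"
    return EnvLayer(name, pc, month=layer.month)


def temporal_composite(monthly: list[EnvLayer], out_month: str = "composite") -> EnvLayer:
    """Per-cell mean over months, skipping missing months cell-wise."""
    if not monthly:
        raise ValueError("temporal_composite needs at least one monthly layer")
    names = {m.variable_name for m in monthly}
    if len(names) > 1:
        raise ValueError(f"mixed variables in composite: {sorted(names)}")
    cube = np.stack([m.values for m in monthly])
    with np.errstate(invalid="ignore"):
        mean = np.where(
            np.isfinite(cube).any(axis=0), np.nanmean(cube, axis=0), np.nan
        )
    return EnvLayer(monthly[0].variable_name, mean, month=out_month)


def standardize(stack: EnvStack) -> EnvStack:
    """Center and scale every layer to mean 0, sd 1 (n-1 denominator).

    The per-variable (mean, sd) pair is recorded on the returned stack so
    raw values can be recovered and prediction-time envelopes expressed on
    either scale.  Already-standardized stacks pass through unchanged
    (idempotent up to floating point).
    """
    out = EnvStack(stack.grid)
    for name in stack.variable_names:
        layer = stack.layers[name]
        vals = layer.values
        finite = vals[np.isfinite(vals)]
        if finite.size < 2:
            raise ValueError(f"layer {name!r} has fewer than 2 defined cells")
        mu = float(finite.mean())
        sd = float(finite.std(ddof=1))
        if sd == 0:
            raise ValueError(f"layer {name!r} is constant; cannot standardize")
        out.add(replace(layer, values=(vals - mu) / sd))
        out.standardization[name] = (mu, sd)
    return out


def spearman_screen(stack: EnvStack, threshold: float = 0.5) -> pd.DataFrame:
    """All pairwise Spearman rank correlations between layers.

    Returns a DataFrame with columns ``var_a, var_b, rs, n, flagged`` where
    ``flagged`` marks |rs| > ``threshold``.  Strongly correlated pairs are
    reported for diagnosis; nothing is excluded automatically.
    """
    names = stack.variable_names
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa = stack.layers[a].values.ravel()
            xb = stack.layers[b].values.ravel()
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < 3:
                raise ValueError(
                    f"pair ({a}, {b}) has only {int(ok.sum())} overlapping cells"
                )
            rs = stats.spearmanr(xa[ok], xb[ok]).statistic
            rows.append(
                {"var_a": a, "var_b": b, "rs": float(rs), "n": int(ok.sum()),
                 "flagged": bool(abs(rs) > threshold)}
            )
    return pd.DataFrame(rows, columns=["var_a", "var_b", "rs", "n", "flagged"])
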