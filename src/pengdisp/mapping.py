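"""Habitat-probability maps from a fitted model.

The selected GLM is projected over every grid cell with complete
covariates, masking cells outside the model's environmental space (the
per-covariate min-max box spanned by the training cells).  The
probability surface can be reduced to three classes for interpretation:
low (< 0.33), medium (0.33-0.66, both endpoints included) and high
(> 0.66).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .env import EnvStack
from .grid import GridSpec
from .sdm import FittedModel

__all__ = [
    "CATEGORY_CODES",
    "PredictionMap",
    "training_envelope",
    "predict_map",
    "categorize",
    "export_map",
    "load_map",
]

#: Encoding of the categorical raster.
CATEGORY_CODES = {"masked": 255, "low": 0, "medium": 1, "high": 2}
_CODE_NAMES = {v: k for k, v in CATEGORY_CODES.items()}

LOW_THRESHOLD = 0.33
HIGH_THRESHOLD = 0.66


@dataclass
class PredictionMap:
    """Per-cell occupancy probability (NaN = masked) and, once
    categorized, the three-class surface."""

    grid: GridSpec
    probability: np.ndarray
    category: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.probability)


def training_envelope(stack: EnvStack, cells, terms) -> dict[str, tuple[float, float]]:
    """Per-covariate [min, max] box over the training cells."""
    X = stack.design_matrix(cells, terms)
    return {
        t: (float(np.nanmin(X[:, j])), float(np.nanmax(X[:, j])))
        for j, t in enumerate(terms)
    }


def predict_map(
    model: FittedModel,
    stack: EnvStack,
    envelope: dict[str, tuple[float, float]] | None = None,
) -> PredictionMap:
    """Inverse-logit of the model's linear predictor on every cell.

    Cells with any model covariate missing — or, when ``envelope`` is
    given, outside the training min-max box — are masked.
    """
    grid = stack.grid
    missing = [t for t in model.terms if t not in stack]
    if missing:
        raise KeyError(f"stack lacks layers for model terms: {missing}")
    eta = np.full(grid.shape, model.coefficients["intercept"], dtype=float)
    ok = np.ones(grid.shape, dtype=bool)
    for t in model.terms:
        vals = stack[t].values
        ok &= np.isfinite(vals)
        if envelope is not None:
            lo, hi = envelope[t]
            ok &= (vals >= lo) & (vals <= hi)
        eta = eta + model.coefficients[t] * np.where(np.isfinite(vals), vals, 0.0)
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-eta))
    prob[~ok] = np.nan
    return PredictionMap(
        grid=grid,
        probability=prob,
        provenance={
            "terms": list(model.terms),
            "coefficients": dict(model.coefficients),
            "envelope": {k: list(v) for k, v in (envelope or {}).items()},
        },
    )


def categorize(
    pmap: PredictionMap,
    low: float = LOW_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> PredictionMap:
    """Three-class surface: p < low -> low, low <= p <= high -> medium,
    p > high -> high; masked cells stay masked."""
    if not low < high:
        raise ValueError(f"thresholds out of order: {low} >= {high}")
    p = pmap.probability
    cat = np.full(p.shape, CATEGORY_CODES["masked"], dtype=np.uint8)
    ok = np.isfinite(p)
    cat[ok & (p < low)] = CATEGORY_CODES["low"]
    cat[ok & (p >= low) & (p <= high)] = CATEGORY_CODES["medium"]
    cat[ok & (p > high)] = CATEGORY_CODES["high"]
    pmap.category = cat
    pmap.provenance["thresholds"] = [low, high]
    return pmap


def category_areas(pmap: PredictionMap) -> dict[str, int]:
    """Cell counts per class (excluding masked)."""
    if pmap.category is None:
        raise ValueError("map not categorized yet")
    return {
        name: int((pmap.category == code).sum())
        for name, code in CATEGORY_CODES.items()
        if name != "masked"
    }


def export_map(pmap: PredictionMap, path) -> None:
    """Write probability and (if present) category rasters to NetCDF with
    the grid's georeferencing; the round trip is bit-exact."""
    g = pmap.grid
    data = {"probability": (("lat", "lon"), pmap.probability)}
    if pmap.category is not None:
        data["category"] = (("lat", "lon"), pmap.category)
    ds = xr.Dataset(
        data,
        coords={"lon": g.lon_centers(), "lat": g.lat_centers()},
        attrs={
            "lon_min": g.lon_min, "lon_max": g.lon_max,
            "lat_min": g.lat_min, "lat_max": g.lat_max,
            "cell_deg": g.cell_deg, "crs": "EPSG:4326",
            "category_codes": str(CATEGORY_CODES),
        },
    )
    ds["probability"].encoding["_FillValue"] = None
    ds.to_netcdf(path)


def load_map(path) -> PredictionMap:
    with xr.open_dataset(path, mask_and_scale=False) as ds:
        ds = ds.load()
    a = ds.attrs
    grid = GridSpec(a["lon_min"], a["lon_max"], a["lat_min"], a["lat_max"],
                    a["cell_deg"])
    cat = ds["category"].values.astype(np.uint8) if "category" in ds else None
    return PredictionMap(grid=grid, probability=ds["probability"].values,
                         category=cat)
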