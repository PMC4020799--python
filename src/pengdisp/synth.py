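"""Synthetic study generator: environmental fields, habitat-biased tracks
and Argos-like observations with known ground truth.

The real tracking data and satellite layers behind the study are not
public, so every downstream stage is exercised on data simulated here
under the study conditions: a 0.04-degree lattice over 10W-110W x
40S-75S, candidate variables within their observed ranges (bathymetry
0-7958 m, chlorophyll-a 0-24.91 mg m-3, SST 0-21.32 degC, SSH
46.30-51.29 cm), transmitters on a 4 h on / 20 h off duty cycle from
01:00 GMT, and Argos location classes 0-3 with positional error scales of
1.5, 1.0, 0.35 and 0.15 km.

Environmental fields are Gaussian-smoothed white noise rescaled to the
target range — the simplest construction with a controllable spatial
correlation length.  Movement is a daily-step biased correlated random
walk: lognormal step lengths around a 45 km/day mean (the cohort's
observed mean daily distance), von Mises directional persistence, and an
exponential pull toward higher habitat suitability.  Occupancy ground
truth is a logistic model on the standardized covariates, mirroring the
form of the fitted GLMs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .env import EnvLayer, EnvStack, canonical_name, gradient_pc, temporal_composite
from .grid import GridSpec
from .tracks import DUTY_CYCLE_START_HOUR, EARTH_RADIUS_KM

__all__ = [
    "EnvFieldSpec",
    "TABLE_RANGES",
    "DEFAULT_FIELD_SPECS",
    "TrueHabitatModel",
    "SimConfig",
    "generate_env_layers",
    "build_env_stack",
    "simulate_track",
    "apply_argos_observation",
    "sample_presence_cells",
    "simulate_study",
]

_KM_PER_DEG = float(np.pi * EARTH_RADIUS_KM / 180.0)  # 111.1949 km

#: Observed (min, max) range of each base variable, in its native units.
TABLE_RANGES: dict[str, tuple[float, float]] = {
    "BAT": (0.0, 7958.0),
    "CHLA": (0.0, 24.91),
    "SST": (0.0, 21.32),
    "SSH": (46.30, 51.29),
}


@dataclass(frozen=True)
class EnvFieldSpec:
    """Recipe for one synthetic environmental variable.

    ``smoothness`` is the spatial correlation length in grid cells (a
    Gaussian kernel sigma); 0 gives spatially white noise.  ``months``
    lists the month labels to generate ("static" variables use a single
    label).
    """

    variable_name: str
    value_range: tuple[float, float]
    smoothness: float = 6.0
    months: tuple[str, ...] = ("2008-01", "2008-02", "2008-03")

    def __post_init__(self) -> None:
        lo, hi = self.value_range
        if lo > hi:
            raise ValueError(f"{self.variable_name}: min {lo} > max {hi}")
        if self.smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        object.__setattr__(self, "variable_name", canonical_name(self.variable_name))


def _default_specs() -> tuple[EnvFieldSpec, ...]:
    return (
        EnvFieldSpec("BAT", TABLE_RANGES["BAT"], smoothness=8.0, months=("static",)),
        EnvFieldSpec("CHLA", TABLE_RANGES["CHLA"]),
        EnvFieldSpec("SST", TABLE_RANGES["SST"]),
        EnvFieldSpec("SSH", TABLE_RANGES["SSH"]),
    )


DEFAULT_FIELD_SPECS = _default_specs()


@dataclass(frozen=True)
class TrueHabitatModel:
    """Ground-truth logistic occupancy model on standardized covariates.

    ``coefficients`` maps term names (canonical variable codes, plus
    "intercept") to their values; suitability is the inverse logit of the
    linear predictor.
    """

    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        coefs = {("intercept" if k.lower() == "intercept" else canonical_name(k)): v
                 for k, v in self.coefficients.items()}
        coefs.setdefault("intercept", 0.0)
        object.__setattr__(self, "coefficients", coefs)

    @property
    def terms(self) -> list[str]:
        return sorted(k for k in self.coefficients if k != "intercept")

    def linear_predictor(self, stack: EnvStack) -> np.ndarray:
        eta = np.full(stack.grid.shape, self.coefficients["intercept"], dtype=float)
        for term in self.terms:
            eta = eta + self.coefficients[term] * stack[term].values
        return eta

    def suitability(self, stack: EnvStack) -> EnvLayer:
        """Per-cell occupancy probability on the stack's grid (NaN where
        any covariate is missing)."""
        eta = self.linear_predictor(stack)
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-eta))
        return EnvLayer("suitability", p)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"coefficients": self.coefficients, "link": "logit"}, fh,
                      indent=2, sort_keys=True)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the simulator.

    Defaults follow the deployment: two colonies (Volunteer Beach,
    Falkland Islands, 10 birds from 11 Dec 2007; St Andrews Bay, South
    Georgia, 8 birds from 13 Dec 2007), ~45 km mean daily displacement,
    4 h on / 20 h off transmitter duty cycle, and class-dependent Argos
    error scales.  Class probabilities are weighted so that, combined
    with the per-window fix count, about 98.6% of daily best positions
    are class 1 or better.
    """

    colonies: tuple[tuple[str, float, float, str, int], ...] = (
        ("FI", -57.833, -51.483, "2007-12-11", 10),
        ("SG", -36.183, -54.45, "2007-12-13", 8),
    )
    step_km_mean: float = 45.0
    step_km_sd: float = 25.0
    turn_concentration: float = 1.0
    habitat_bias: float = 0.0
    duty_on_hours: float = 4.0
    duty_off_hours: float = 20.0
    class_probabilities: dict[int, float] = field(
        default_factory=lambda: {0: 0.17, 1: 0.28, 2: 0.30, 3: 0.25}
    )
    class_error_km: dict[int, float] = field(
        default_factory=lambda: {0: 1.5, 1: 1.0, 2: 0.35, 3: 0.15}
    )
    fixes_per_window_mean: float = 4.0
    n_direction_candidates: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        p = sum(self.class_probabilities.values())
        if abs(p - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {p}, not 1")
        e = self.class_error_km
        # non-strict so the degenerate zero-noise configuration is allowed
        if not (e[0] >= e[1] >= e[2] >= e[3] >= 0):
            raise ValueError("error scales must decrease with class: 0 >= 1 >= 2 >= 3")


# --------------------------------------------------------------- env fields

def generate_env_layers(spec: EnvFieldSpec, grid: GridSpec, seed: int) -> list[EnvLayer]:
    """One spatially autocorrelated layer per month in ``spec.months``.

    Gaussian white noise is smoothed with a kernel of sigma
    ``spec.smoothness`` cells and rescaled linearly onto
    ``spec.value_range`` (so the range is respected exactly).  Bit
    deterministic for a given seed.
    """
    from scipy.ndimage import gaussian_filter

    lo, hi = spec.value_range
    ss = np.random.SeedSequence([seed, _stable_hash(spec.variable_name)])
    layers = []
    for month, child in zip(spec.months, ss.spawn(len(spec.months))):
        rng = np.random.default_rng(child)
        z = rng.standard_normal(grid.shape)
        if spec.smoothness > 0:
            z = gaussian_filter(z, sigma=spec.smoothness, mode="reflect")
        zmin, zmax = z.min(), z.max()
        if zmax > zmin:
            z = (z - zmin) / (zmax - zmin)
        else:  # degenerate constant field
            z = np.zeros_like(z)
        layers.append(EnvLayer(spec.variable_name, lo + z * (hi - lo), month=month))
    return layers


def _stable_hash(name: str) -> int:
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def build_env_stack(
    grid: GridSpec,
    seed: int,
    specs: tuple[EnvFieldSpec, ...] = DEFAULT_FIELD_SPECS,
) -> EnvStack:
    """Composite the monthly fields, add 3x3 proportional-change gradients,
    and return the raw (unstandardized) eight-variable stack."""
    stack = EnvStack(grid)
    for spec in specs:
        monthly = generate_env_layers(spec, grid, seed)
        base = temporal_composite(monthly) if len(monthly) > 1 else monthly[0]
        base = EnvLayer(spec.variable_name, base.values)
        stack.add(base)
        # PC gradient needs non-negative input; all default ranges are.
        shift = min(0.0, float(np.nanmin(base.values)))
        grad_src = base if shift == 0 else EnvLayer(base.variable_name,
                                                    base.values - shift)
        stack.add(gradient_pc(grad_src, out_name=f"{spec.variable_name}.G3"))
    return stack


# ------------------------------------------------------------------ movement

def simulate_track(
    config: SimConfig,
    suitability: EnvLayer,
    grid: GridSpec,
    colony_index: int,
    n_days: int,
    seed: int,
) -> pd.DataFrame:
    """Daily true positions of one bird leaving its colony.

    A biased correlated random walk: each day a lognormal step length
    (mean ``step_km_mean``, sd ``step_km_sd``) and a heading drawn by
    scoring ``n_direction_candidates`` von Mises proposals (concentration
    ``turn_concentration`` about the previous heading) with weight
    exp(habitat_bias * suitability at the destination).  With zero bias
    the walk is a plain correlated random walk; with zero concentration
    headings are uniform.

    Returns a DataFrame (bird_id, date, lon, lat) with one row per day.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    name, lon0, lat0, dep, _ = config.colonies[colony_index]
    r, c = grid.point_to_cell(lon0, lat0)
    if r < 0:
        raise ValueError(f"colony {name} at ({lon0}, {lat0}) lies outside the grid")
    suit = suitability.values
    if not np.isfinite(suit).any():
        raise ValueError("suitability is undefined everywhere")

    rng = np.random.default_rng(np.random.SeedSequence([seed, colony_index]))
    mean, sd = config.step_km_mean, config.step_km_sd
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    kappa = config.turn_concentration
    m = config.n_direction_candidates

    lon, lat = float(lon0), float(lat0)
    heading = rng.uniform(0.0, 2.0 * np.pi)
    start = date.fromisoformat(dep)
    rows = []
    for day in range(n_days):
        step_km = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if kappa > 0:
            thetas = heading + rng.vonmises(0.0, kappa, size=m)
        else:
            thetas = rng.uniform(0.0, 2.0 * np.pi, size=m)
        dlat = step_km * np.sin(thetas) / _KM_PER_DEG
        dlon = step_km * np.cos(thetas) / (
            _KM_PER_DEG * np.cos(np.radians(lat))
        )
        cand_lon, cand_lat = lon + dlon, lat + dlat
        rr, cc = grid.point_to_cell(cand_lon, cand_lat)
        valid = rr >= 0
        s = np.full(m, np.nan)
        s[valid] = suit[rr[valid], cc[valid]]
        finite = np.isfinite(s)
        w = np.zeros(m)
        if finite.any():
            w[finite] = np.exp(config.habitat_bias * (s[finite] - s[finite].max()))
        if w.sum() == 0:
            # every proposal leaves the defined region: fall back on the
            # proposal pointing most toward the grid center
            center = (0.5 * (grid.lon_min + grid.lon_max),
                      0.5 * (grid.lat_min + grid.lat_max))
            k = int(np.argmin((cand_lon - center[0]) ** 2
                              + (cand_lat - center[1]) ** 2))
        else:
            k = int(rng.choice(m, p=w / w.sum()))
        heading = float(thetas[k])
        lon, lat = float(cand_lon[k]), float(cand_lat[k])
        rows.append({"bird_id": f"{name}-{colony_index}",
                     "date": start + timedelta(days=day + 1),
                     "lon": lon, "lat": lat})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- observation

def apply_argos_observation(
    true_positions: pd.DataFrame, config: SimConfig, seed: int
) -> pd.DataFrame:
    """Degrade true daily positions into Argos-like fixes.

    Each day yields 1 + Poisson(fixes_per_window_mean - 1) fixes, all
    timestamped inside that day's 4-hour on-window (starting 01:00 GMT).
    Each fix draws a location class from ``class_probabilities`` and
    isotropic Gaussian position noise whose RMS displacement equals the
    class's error scale in km.
    """
    if true_positions.empty:
        raise ValueError("no true positions to observe")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    classes = sorted(config.class_probabilities)
    probs = np.array([config.class_probabilities[c] for c in classes])
    lam = max(config.fixes_per_window_mean - 1.0, 0.0)

    rows = []
    for rec in true_positions.sort_values("date").itertuples(index=False):
        n_fix = 1 + int(rng.poisson(lam))
        offsets = np.sort(rng.uniform(0.0, config.duty_on_hours, size=n_fix))
        base = pd.Timestamp(rec.date, tz="UTC") + pd.Timedelta(
            hours=DUTY_CYCLE_START_HOUR
        )
        for off in offsets:
            klass = int(rng.choice(classes, p=probs))
            scale = config.class_error_km[klass]
            sigma_km = scale / np.sqrt(2.0)  # per-axis, so RMS radius = scale
            dy, dx = rng.normal(0.0, sigma_km, size=2)
            lat = rec.lat + dy / _KM_PER_DEG
            lon = rec.lon + dx / (_KM_PER_DEG * np.cos(np.radians(rec.lat)))
            rows.append({
                "bird_id": rec.bird_id,
                "timestamp": base + pd.Timedelta(hours=float(off)),
                "lon": lon,
                "lat": lat,
                "location_class": klass,
            })
    return pd.DataFrame(rows)


# -------------------------------------------------------------- occupancy

def sample_presence_cells(
    model: TrueHabitatModel, stack: EnvStack, n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` distinct presence cells with probability proportional to
    the ground-truth suitability (on the standardized stack)."""
    cells = stack.complete_cells(model.terms)
    if cells.size < n:
        raise ValueError(f"only {cells.size} candidate cells for {n} presences")
    suit = model.suitability(stack).values.ravel()[cells]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    p = suit / suit.sum()
    return np.sort(rng.choice(cells, size=n, replace=False, p=p))


# ------------------------------------------------------------- whole study

def simulate_study(
    grid: GridSpec,
    config: SimConfig,
    n_days: int = 110,
    seed: int | None = None,
) -> tuple[EnvStack, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic deployment: raw env stack, true daily
    positions for every bird at both colonies, and Argos fixes.

    Returns ``(raw_stack, true_positions, fixes)``.
    """
    seed = config.seed if seed is None else seed
    stack = build_env_stack(grid, seed)
    # habitat bias follows a mildly attractive mixture of the base fields
    from .env import standardize

    std = standardize(stack)
    bias_model = TrueHabitatModel(
        {"BAT": 1.0, "SST": -1.0, "CHLA": 1.0, "intercept": 0.0}
    )
    suit = bias_model.suitability(std)

    truths, fixes = [], []
    bird = 0
    for ci, (_, _, _, _, n_birds) in enumerate(config.colonies):
        for b in range(n_birds):
            t = simulate_track(config, suit, grid, ci, n_days,
                               seed=seed * 1000 + bird)
            t = t.assign(bird_id=f"{config.colonies[ci][0]}-{b:02d}")
            truths.append(t)
            fixes.append(apply_argos_observation(t, config,
                                                 seed=seed * 1000 + bird))
            bird += 1
    return stack, pd.concat(truths, ignore_index=True), pd.concat(
        fixes, ignore_index=True
    )
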