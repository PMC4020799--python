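"""Presence cells and masked pseudo-absence designs.

Daily positions inside the modelling window (1 Jan - 31 Mar 2008 for the
study) are rasterized onto the analysis lattice; each occupied cell
counts once.  Pseudo-absences are drawn from "surveyed" cells — here,
every grid cell with complete environmental data — excluding presences
and their 3x3 neighborhoods, with the same number of absences as
presences per set, sampled without replacement within a set and
independently across the 100 sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = [
    "MODEL_WINDOW",
    "PresenceSet",
    "PseudoAbsenceDesign",
    "rasterize_presence",
    "presence_mask",
    "sample_pseudo_absences",
]

#: The study's GLM modelling window.
MODEL_WINDOW = (date(2008, 1, 1), date(2008, 3, 31))


@dataclass
class PresenceSet:
    """Grid cells occupied at least once inside the window."""

    colony: str
    window: tuple[date, date]
    cells: np.ndarray  # sorted scalar cell ids
    n_positions_used: int
    n_outside_window: int
    n_outside_grid: int

    @property
    def n_cells(self) -> int:
        return int(self.cells.size)


@dataclass
class PseudoAbsenceDesign:
    """Candidate background cells and the replicate pseudo-absence sets."""

    candidate_cells: np.ndarray
    sets: list[np.ndarray]
    seed: int
    masked_cells: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_sets(self) -> int:
        return len(self.sets)


def rasterize_presence(
    daily: pd.DataFrame,
    grid: GridSpec,
    window: tuple[date, date] = MODEL_WINDOW,
    colony: str = "",
) -> PresenceSet:
    """Map daily positions in the window onto unique presence cells.

    Positions dated outside the window or falling off the grid are
    excluded and counted in the returned diagnostics.  Raises if nothing
    remains.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window start after window end")
    dates = pd.to_datetime(daily["date"]).dt.date
    in_window = (dates >= lo) & (dates <= hi)
    sub = daily[in_window]
    row, col = grid.point_to_cell(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    on_grid = row >= 0
    cells = np.unique(row[on_grid] * grid.n_cols + col[on_grid])
    n_out_win = int((~in_window).sum())
    n_out_grid = int((~on_grid).sum())
    if cells.size == 0:
        raise ValueError(
            f"no presence cells: {len(daily)} positions, {n_out_win} outside "
            f"window, {n_out_grid} outside grid"
        )
    return PresenceSet(colony, window, cells, int(on_grid.sum()),
                       n_out_win, n_out_grid)


def presence_mask(presences: PresenceSet, grid: GridSpec) -> np.ndarray:
    """Cells unavailable for pseudo-absence: the union of 3x3 windows
    around every presence cell (truncated at the grid edge)."""
    if presences.cells.size == 0:
        return np.empty(0, dtype=int)
    r = presences.cells // grid.n_cols
    c = presences.cells % grid.n_cols
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr, cc = r + dr, c + dc
            ok = (rr >= 0) & (rr < grid.n_rows) & (cc >= 0) & (cc < grid.n_cols)
            out.append(rr[ok] * grid.n_cols + cc[ok])
    return np.unique(np.concatenate(out))


def sample_pseudo_absences(
    presences: PresenceSet,
    env_complete_cells: np.ndarray,
    grid: GridSpec,
    n_sets: int = 100,
    seed: int = 0,
) -> PseudoAbsenceDesign:
    """Draw ``n_sets`` balanced pseudo-absence sets.

    Candidates are the data-complete cells minus the presence mask; each
    set holds exactly as many distinct cells as there are presences,
    drawn uniformly without replacement, independently across sets.
    Deterministic for a given seed.
    """
    masked = presence_mask(presences, grid)
    candidates = np.setdiff1d(np.asarray(env_complete_cells, dtype=int), masked)
    n = presences.n_cells
    if candidates.size < n:
        raise ValueError(
            f"only {candidates.size} candidate cells for {n} pseudo-absences "
            f"(short by {n - candidates.size})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    sets = [np.sort(rng.choice(candidates, size=n, replace=False))
            for _ in range(n_sets)]
    return PseudoAbsenceDesign(candidates, sets, seed, masked_cells=masked)


def design_frame(presences: PresenceSet, design: PseudoAbsenceDesign,
                 grid: GridSpec) -> pd.DataFrame:
    """Long-format table of presence and pseudo-absence cells for export:
    columns cell_id, row, col, lon_center, lat_center, set_index (-1 for
    presences)."""
    recs = [(presences.cells, -1)] + [
        (s, i) for i, s in enumerate(design.sets)
    ]
    frames = []
    for cells, idx in recs:
        r, c = grid.id_to_rowcol(cells)
        lon, lat = grid.cell_center(cells)
        frames.append(pd.DataFrame({
            "cell_id": cells, "row": r, "col": c,
            "lon_center": lon, "lat_center": lat, "set_index": idx,
        }))
    return pd.concat(frames, ignore_index=True)
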