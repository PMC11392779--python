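"""Occurrence gridding, sampling redundancy and resolution selection.

Point records are binned into a regular grid of square cells (planar,
already-projected coordinates; half-open [lo, hi) cell intervals so a point
on a boundary belongs to the higher-index cell).  Sampling completeness per
cell is summarised by redundancy, 1 − richness/samples: 0 means one record
per species (poor sampling), values approaching 1 mean heavy resampling.
The working resolution is the finest candidate whose average redundancy over
non-empty cells (ARd) reaches the acceptability threshold (default 0.6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidConfigError

__all__ = [
    "GridSpec",
    "PresenceMatrix",
    "RedundancyReport",
    "grid_from_extent",
    "assign_to_cells",
    "range_filter",
    "compute_redundancy",
    "select_resolution",
    "DEFAULT_CANDIDATE_SIZES",
]

#: candidate cell sizes (km) evaluated during resolution selection
DEFAULT_CANDIDATE_SIZES: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class GridSpec:
    """A regular grid of square cells, indexed row-major from the origin."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidConfigError("grid must have at least one cell")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Flat row-major cell index per point; −1 for out-of-extent points."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_size)
        inside = (
            (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        )
        flat = np.where(inside, row * self.n_cols + col, -1)
        return flat.astype(int)

    def rowcol(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        flat = np.asarray(flat)
        return flat // self.n_cols, flat % self.n_cols

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) cell centroids, row-major order."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (rows + 0.5) * self.cell_size
        return np.column_stack([x, y])


@dataclass
class PresenceMatrix:
    """Cells × species boolean occupancy plus per-cell raw record counts."""

    grid: GridSpec
    presence: np.ndarray  # (n_cells, n_species) bool
    samples: np.ndarray   # (n_cells,) int — raw record count per cell
    species: list[str]
    n_dropped_records: int = 0

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.samples = np.asarray(self.samples, dtype=int)
        richness = self.presence.sum(axis=1)
        if np.any(self.samples < richness):
            raise ValueError("samples must be >= richness in every cell")

    @property
    def richness(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of non-empty cells."""
        return self.richness > 0

    def range_sizes(self) -> np.ndarray:
        """Occupied-cell count per species."""
        return self.presence.sum(axis=0)


@dataclass
class RedundancyReport:
    """Per-cell redundancy and its average over non-empty cells."""

    per_cell: np.ndarray      # NaN for empty cells
    average: float            # ARd: unweighted mean over non-empty cells
    n_nonempty: int
    cell_size: float | None = None

    def low_cells(self, threshold: float = 0.6) -> np.ndarray:
        """Mask of non-empty cells whose redundancy is below ``threshold``."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.per_cell, nan=np.inf) < threshold


def grid_from_extent(
    occurrences: pd.DataFrame,
    cell_size: float,
    origin: tuple[float, float] | None = None,
) -> GridSpec:
    """Build the smallest grid of ``cell_size`` cells covering all points.

    The default origin is the (min x, min y) corner of the point cloud, so
    every record is in-extent under the half-open convention.
    """
    x = occurrences["x"].to_numpy(float)
    y = occurrences["y"].to_numpy(float)
    if x.size == 0 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise EmptyInputError("occurrences must contain finite coordinates")
    if origin is None:
        origin = (float(x.min()), float(y.min()))
    n_cols = int(np.floor((x.max() - origin[0]) / cell_size)) + 1
    n_rows = int(np.floor((y.max() - origin[1]) / cell_size)) + 1
    return GridSpec(origin[0], origin[1], cell_size, n_rows, n_cols)


def assign_to_cells(
    occurrences: pd.DataFrame, grid: GridSpec
) -> PresenceMatrix:
    """Bin (species, x, y) records into a presence matrix.

    Records outside the grid extent are counted and dropped with a warning;
    species with no in-extent records are dropped (with a warning) so every
    presence column has at least one occupied cell.
    """
    x = occurrences["x"].to_numpy(float)
    y = occurrences["y"].to_numpy(float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("coordinates must be finite")
    flat = grid.cell_index(x, y)
    inside = flat >= 0
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"{n_out} records outside grid extent dropped",
                      stacklevel=2)
    if not inside.any():
        raise EmptyInputError("no occurrence records fall inside the grid")
    flat_in = flat[inside]
    sp_in = occurrences["species"].to_numpy()[inside]

    species = sorted(pd.unique(sp_in))
    col_of = {s: j for j, s in enumerate(species)}
    presence = np.zeros((grid.n_cells, len(species)), dtype=bool)
    presence[flat_in, [col_of[s] for s in sp_in]] = True

    all_species = set(pd.unique(occurrences["species"]))
    lost = sorted(all_species - set(species))
    if lost:
        warnings.warn(
            f"{len(lost)} species had no in-extent records and were dropped",
            stacklevel=2,
        )
    samples = np.bincount(flat_in, minlength=grid.n_cells)
    return PresenceMatrix(grid, presence, samples, species,
                          n_dropped_records=n_out)


def range_filter(
    occurrences: pd.DataFrame, bounds: pd.DataFrame | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records outside a species' declared bounding box.

    ``bounds`` columns: species, xmin, xmax, ymin, ymax (one row per species
    with known range).  Species without bounds pass through untouched.
    Returns (kept records, drop log).
    """
    if bounds is None or len(bounds) == 0:
        return occurrences.copy(), occurrences.iloc[0:0].copy()
    merged = occurrences.merge(bounds, on="species", how="left")
    no_bounds = merged["xmin"].isna()
    ok = no_bounds | (
        (merged["x"] >= merged["xmin"]) & (merged["x"] <= merged["xmax"])
        & (merged["y"] >= merged["ymin"]) & (merged["y"] <= merged["ymax"])
    )
    kept = occurrences.loc[ok.to_numpy()].copy()
    dropped = occurrences.loc[(~ok).to_numpy()].copy()
    return kept, dropped


def compute_redundancy(pm: PresenceMatrix) -> RedundancyReport:
    """Per-cell redundancy 1 − richness/samples; ARd over non-empty cells."""
    richness = pm.richness.astype(float)
    occupied = richness > 0
    if not occupied.any():
        raise EmptyInputError("presence matrix has no occupied cells")
    per_cell = np.full(pm.grid.n_cells, np.nan)
    per_cell[occupied] = 1.0 - richness[occupied] / pm.samples[occupied]
    return RedundancyReport(
        per_cell=per_cell,
        average=float(per_cell[occupied].mean()),
        n_nonempty=int(occupied.sum()),
        cell_size=pm.grid.cell_size,
    )


def select_resolution(
    occurrences: pd.DataFrame,
    candidate_sizes: tuple[float, ...] = DEFAULT_CANDIDATE_SIZES,
    ard_threshold: float = 0.6,
    origin: tuple[float, float] | None = None,
) -> tuple[GridSpec, pd.DataFrame, bool]:
    """Choose the working grid resolution by average redundancy.

    Among candidates whose ARd reaches ``ard_threshold``, the smallest cell
    size (finest grid) wins; if none qualifies, the candidate with the
    highest ARd is returned and the ``below_threshold`` flag is set.

    Returns (chosen grid, per-resolution report, below_threshold).
    """
    if not candidate_sizes:
        raise InvalidConfigError("candidate_sizes must be non-empty")
    rows = []
    grids: dict[float, GridSpec] = {}
    for size in candidate_sizes:
        grid = grid_from_extent(occurrences, size, origin=origin)
        pm = assign_to_cells(occurrences, grid)
        report = compute_redundancy(pm)
        grids[size] = grid
        rows.append({
            "cell_size": size,
            "ard": report.average,
            "n_nonempty_cells": report.n_nonempty,
            "passes": report.average >= ard_threshold,
        })
    table = pd.DataFrame(rows).sort_values("cell_size").reset_index(drop=True)
    passing = table.loc[table["passes"], "cell_size"]
    if len(passing):
        chosen = float(passing.min())
        return grids[chosen], table, False
    chosen = float(table.loc[table["ard"].idxmax(), "cell_size"])
    return grids[chosen], table, True
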