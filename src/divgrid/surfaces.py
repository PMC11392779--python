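"""Assembly of the six per-cell metric surfaces and low-redundancy filling.

The six surfaces are species richness (TD), weighted endemism (WE = per-cell
sum of inverse range sizes), Faith-style phylogenetic diversity (PD) and
phylogenetic endemism (PE) on the dated tree, and their functional analogues
(FD, FE) on the UPGMA trait dendrogram.  Empty cells carry NaN, never zero.

Cells whose sampling redundancy falls below the acceptability threshold are
optionally replaced by an inverse-distance-squared weighted mean of
well-sampled cells within a small Chebyshev neighborhood (a deterministic
stand-in for geostatistical interpolation; the interpolator is pluggable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .functional import fd_fe_surfaces
from .grid import GridSpec, PresenceMatrix, RedundancyReport, compute_redundancy
from .trees import BranchTable, RootedTree

__all__ = [
    "SurfaceSet",
    "METRICS",
    "taxonomic_surfaces",
    "compute_all_surfaces",
    "interpolate_low_redundancy",
]

METRICS = ("TD", "FD", "PD", "WE", "FE", "PE")


@dataclass
class SurfaceSet:
    """The six per-cell metric surfaces on a common grid."""

    grid: GridSpec
    values: dict[str, np.ndarray]          # metric -> (n_cells,) float, NaN = missing
    redundancy: RedundancyReport
    low_redundancy: np.ndarray             # bool mask over cells
    interpolated: np.ndarray = field(default=None)  # bool mask over cells
    log: list[dict] = field(default_factory=list)
    mode: str = "root"

    def __post_init__(self) -> None:
        if self.interpolated is None:
            self.interpolated = np.zeros(self.grid.n_cells, dtype=bool)
        for name in METRICS:
            if name not in self.values:
                raise ValueError(f"missing surface {name}")
            if self.values[name].shape != (self.grid.n_cells,):
                raise ValueError(f"surface {name} has wrong shape")

    def as_frame(self):
        """Long-format table: row, col, metric, value, flags."""
        import pandas as pd

        rows, cols = self.grid.rowcol(np.arange(self.grid.n_cells))
        frames = []
        for name in METRICS:
            frames.append(pd.DataFrame({
                "row": rows, "col": cols, "metric": name,
                "value": self.values[name],
                "low_redundancy": self.low_redundancy,
                "interpolated": self.interpolated,
            }))
        return pd.concat(frames, ignore_index=True)


def taxonomic_surfaces(pm: PresenceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell TD (richness) and WE (sum of inverse range sizes).

    WE(c) = Σ_{s in c} 1/|range_s| with |range_s| the number of occupied
    cells of species s; summed over all cells it equals the number of
    occurring species.  NaN for empty cells.
    """
    td = pm.richness.astype(float)
    ranges = pm.range_sizes().astype(float)
    we = pm.presence @ (1.0 / ranges)
    empty = ~pm.occupied
    td[empty] = np.nan
    we[empty] = np.nan
    return td, we


def compute_all_surfaces(
    pm: PresenceMatrix,
    tree: RootedTree,
    dendrogram: RootedTree,
    mode: str = "root",
    ard_threshold: float = 0.6,
) -> SurfaceSet:
    """Compute TD/WE, PD/PE (phylogeny) and FD/FE (dendrogram) per cell."""
    occurring = {s for s, r in zip(pm.species, pm.range_sizes()) if r > 0}
    for name, t in (("phylogeny", tree), ("dendrogram", dendrogram)):
        diff = occurring.symmetric_difference(t.leaf_labels) & occurring
        if diff:
            raise ValueError(
                f"species present in cells but absent from {name}: "
                f"{sorted(diff)}"
            )
    td, we = taxonomic_surfaces(pm)
    ptable = BranchTable(tree, pm.presence, pm.species)
    pd_, pe = ptable.pd_per_cell(mode), ptable.endemism_per_cell(mode)
    fd, fe = fd_fe_surfaces(dendrogram, pm.presence, pm.species, mode=mode)
    redundancy = compute_redundancy(pm)
    low = redundancy.low_cells(ard_threshold)
    return SurfaceSet(
        grid=pm.grid,
        values={"TD": td, "FD": fd, "PD": pd_, "WE": we, "FE": fe, "PE": pe},
        redundancy=redundancy,
        low_redundancy=low,
        mode=mode,
    )


def _idw_fill(
    field2d: np.ndarray, good: np.ndarray, target: np.ndarray, radius: int
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-distance-squared fill of ``target`` cells from ``good`` cells
    within Chebyshev ``radius``.  Returns (filled 2-D field, filled mask)."""
    n_rows, n_cols = field2d.shape
    out = field2d.copy()
    filled = np.zeros_like(good)
    rows, cols = np.nonzero(target)
    for r, c in zip(rows, cols):
        num = den = 0.0
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    continue
                if not good[rr, cc]:
                    continue
                d = max(abs(dr), abs(dc))  # Chebyshev distance in cells
                w = 1.0 / d**2
                num += w * field2d[rr, cc]
                den += w
        if den > 0:
            out[r, c] = num / den
            filled[r, c] = True
        else:
            out[r, c] = np.nan
    return out, filled


def interpolate_low_redundancy(
    surfaces: SurfaceSet,
    neighborhood: int = 2,
    interpolator: Callable[..., tuple[np.ndarray, np.ndarray]] | None = None,
) -> SurfaceSet:
    """Replace the six values of each low-redundancy cell by an
    inverse-distance-squared weighted mean of well-sampled cells within
    Chebyshev radius ``neighborhood``.

    Cells with no qualifying neighbor become NaN and stay flagged; cells at
    or above the threshold are never altered.  Original values are retained
    in the returned set's log.  ``interpolator`` may override the IDW fill
    (same signature as the internal ``_idw_fill``).
    """
    fill = interpolator or _idw_fill
    shape = (surfaces.grid.n_rows, surfaces.grid.n_cols)
    low2d = surfaces.low_redundancy.reshape(shape)
    occupied2d = ~np.isnan(surfaces.values["TD"]).reshape(shape)
    good2d = occupied2d & ~low2d

    new_values: dict[str, np.ndarray] = {}
    interpolated = np.zeros(surfaces.grid.n_cells, dtype=bool)
    log = list(surfaces.log)
    target = low2d & occupied2d
    for name in METRICS:
        field2d = surfaces.values[name].reshape(shape)
        out2d, filled2d = fill(field2d, good2d, target, neighborhood)
        new_values[name] = out2d.ravel().astype(float)
        interpolated |= filled2d.ravel()
    for flat in np.flatnonzero(target.ravel()):
        log.append({
            "cell": int(flat),
            "original": {m: float(surfaces.values[m][flat]) for m in METRICS},
            "filled": bool(interpolated[flat]),
        })
    return SurfaceSet(
        grid=surfaces.grid,
        values=new_values,
        redundancy=surfaces.redundancy,
        low_redundancy=surfaces.low_redundancy,
        interpolated=interpolated,
        log=log,
        mode=surfaces.mode,
    )
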