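"""Point occurrences -> grid-cell assemblages.

Occurrence records (species, x, y in a projected planar CRS, optional region
label) are binned into square cells on a half-open grid, optionally
re-aggregated to coarser cells, filtered by a strict minimum-richness rule,
and restricted to species subsets (e.g. one growth form). Presence is binary:
duplicate records collapse. Coordinate transformation from geographic to
projected systems is deliberately out of scope — records must arrive in
meters.

Region labels are a property of cells, not species; a species can contribute
to several regional pools.
"""

from __future__ import annotations

import io
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_occurrences",
    "AssemblageGrid",
    "grid_occurrences",
    "aggregate_cells",
    "filter_min_richness",
    "restrict_to_species",
    "regional_pools",
    "continental_pool",
]

Cell = tuple[int, int]


def read_occurrences(source) -> pd.DataFrame:
    """Read a delimited occurrence table with header ``species,x,y[,region]``."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype={"species": str, "region": str})
    required = ["species", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if (df["species"].isna() | (df["species"].str.strip() == "")).any():
        raise ValueError("occurrence table contains empty species labels")
    df["x"] = df["x"].astype(float)
    df["y"] = df["y"].astype(float)
    return df


@dataclass
class AssemblageGrid:
    """Grid-cell assemblages: cell index -> species presence set.

    ``cells[(i, j)]`` holds the species present in the half-open square
    ``[x0 + i*s, x0 + (i+1)*s) x [y0 + j*s, y0 + (j+1)*s)``. ``region_of``
    maps cells to region labels when regions are defined. ``n_rejected``
    counts records dropped for non-finite coordinates.
    """

    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    cells: dict[Cell, frozenset[str]] = field(default_factory=dict)
    region_of: dict[Cell, str] = field(default_factory=dict)
    n_rejected: int = 0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def species(self) -> frozenset[str]:
        """All species present anywhere on the grid."""
        out: set[str] = set()
        for s in self.cells.values():
            out |= s
        return frozenset(out)

    def richness(self) -> dict[Cell, int]:
        return {c: len(s) for c, s in self.cells.items()}

    @property
    def has_regions(self) -> bool:
        return bool(self.region_of) and set(self.region_of) >= set(self.cells)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: cell_i, cell_j, region, richness, species (;-joined)."""
        rows = []
        for (i, j) in sorted(self.cells):
            sp = sorted(self.cells[(i, j)])
            rows.append({
                "cell_i": i,
                "cell_j": j,
                "region": self.region_of.get((i, j), ""),
                "richness": len(sp),
                "species": ";".join(sp),
            })
        return pd.DataFrame(rows, columns=["cell_i", "cell_j", "region", "richness", "species"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_size: float,
                   origin: tuple[float, float] = (0.0, 0.0)) -> "AssemblageGrid":
        cells: dict[Cell, frozenset[str]] = {}
        region_of: dict[Cell, str] = {}
        for row in df.itertuples(index=False):
            key = (int(row.cell_i), int(row.cell_j))
            cells[key] = frozenset(str(row.species).split(";"))
            region = getattr(row, "region", None)
            if region is not None and not pd.isna(region) and str(region):
                region_of[key] = str(region)
        return cls(cell_size=cell_size, origin=origin, cells=cells, region_of=region_of)


def _majority_label(labels: Iterable[str]) -> str:
    """Most common label; ties broken by lexicographically smallest."""
    counts = Counter(labels)
    best = max(counts.values())
    return min(l for l, c in counts.items() if c == best)


def grid_occurrences(
    occ: pd.DataFrame,
    cell_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> AssemblageGrid:
    """Bin occurrence records into half-open square cells.

    A record at (x, y) maps to cell ``(floor((x-x0)/s), floor((y-y0)/s))``.
    Records with non-finite coordinates are rejected and counted in
    ``n_rejected``. If the table has a region column, each cell takes the
    majority region label of its records (ties -> smallest label).
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    x0, y0 = origin
    cells: dict[Cell, set[str]] = {}
    cell_regions: dict[Cell, list[str]] = {}
    has_region = "region" in occ.columns
    n_rejected = 0
    for row in occ.itertuples(index=False):
        x, y = float(row.x), float(row.y)
        if not (math.isfinite(x) and math.isfinite(y)):
            n_rejected += 1
            continue
        key = (math.floor((x - x0) / cell_size), math.floor((y - y0) / cell_size))
        cells.setdefault(key, set()).add(row.species)
        if has_region and not pd.isna(row.region) and str(row.region):
            cell_regions.setdefault(key, []).append(str(row.region))
    region_of = {c: _majority_label(ls) for c, ls in cell_regions.items()}
    return AssemblageGrid(
        cell_size=cell_size,
        origin=origin,
        cells={c: frozenset(s) for c, s in cells.items()},
        region_of=region_of,
        n_rejected=n_rejected,
    )


def aggregate_cells(grid: AssemblageGrid, factor: int) -> AssemblageGrid:
    """Re-aggregate to cells ``factor`` times coarser (10 km -> 50 km etc).

    Child cell (i, j) maps to (floor(i/f), floor(j/f)); species sets are
    unioned. The coarse cell keeps the region label all children agree on,
    otherwise the majority label among children (ties -> smallest).
    """
    if not isinstance(factor, int) or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    if factor == 1:
        return AssemblageGrid(
            cell_size=grid.cell_size, origin=grid.origin,
            cells=dict(grid.cells), region_of=dict(grid.region_of),
            n_rejected=grid.n_rejected,
        )
    cells: dict[Cell, set[str]] = {}
    regions: dict[Cell, list[str]] = {}
    for (i, j), sp in grid.cells.items():
        key = (i // factor, j // factor)
        cells.setdefault(key, set()).update(sp)
        if (i, j) in grid.region_of:
            regions.setdefault(key, []).append(grid.region_of[(i, j)])
    return AssemblageGrid(
        cell_size=grid.cell_size * factor,
        origin=grid.origin,
        cells={c: frozenset(s) for c, s in cells.items()},
        region_of={c: _majority_label(ls) for c, ls in regions.items()},
        n_rejected=grid.n_rejected,
    )


def filter_min_richness(grid: AssemblageGrid, min_exclusive: int = 5) -> AssemblageGrid:
    """Keep only cells with strictly more than ``min_exclusive`` species.

    The default mirrors the usual practice of dropping cells with <=5
    species so sparse outlying records do not populate the map.
    """
    if min_exclusive < 0:
        raise ValueError("min_exclusive must be >= 0")
    kept = {c: s for c, s in grid.cells.items() if len(s) > min_exclusive}
    return AssemblageGrid(
        cell_size=grid.cell_size, origin=grid.origin, cells=kept,
        region_of={c: r for c, r in grid.region_of.items() if c in kept},
        n_rejected=grid.n_rejected,
    )


def restrict_to_species(grid: AssemblageGrid, keep: Iterable[str]) -> AssemblageGrid:
    """Intersect every cell with ``keep`` (a species subset); drop emptied cells."""
    keep = frozenset(keep)
    if not keep:
        raise ValueError("keep must be nonempty")
    cells = {}
    for c, s in grid.cells.items():
        inter = s & keep
        if inter:
            cells[c] = inter
    return AssemblageGrid(
        cell_size=grid.cell_size, origin=grid.origin, cells=cells,
        region_of={c: r for c, r in grid.region_of.items() if c in cells},
        n_rejected=grid.n_rejected,
    )


def regional_pools(grid: AssemblageGrid) -> dict[str, frozenset[str]]:
    """Per-region species pools: union of cell sets over each region's cells.

    Every cell must carry a region label.
    """
    unlabelled = sorted(set(grid.cells) - set(grid.region_of))
    if unlabelled:
        raise ValueError(f"cells without region labels: {unlabelled[:10]}"
                         + ("..." if len(unlabelled) > 10 else ""))
    pools: dict[str, set[str]] = {}
    for c, sp in grid.cells.items():
        pools.setdefault(grid.region_of[c], set()).update(sp)
    return {r: frozenset(s) for r, s in pools.items()}


def continental_pool(grid: AssemblageGrid) -> frozenset[str]:
    """Union of species over all cells (the full analyzed species set)."""
    return grid.species
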