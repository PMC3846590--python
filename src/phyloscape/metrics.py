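"""Per-cell diversity metrics.

For each grid cell with species set C on a dated phylogeny:

* richness  S = |C|
* Faith PD  = sum of branch lengths of the minimal subtree spanning C,
  root path included by default (so single-species PD is the tip-to-root
  path; an ``include_root=False`` flag drops the shared root path)
* Rosauer PE = sum over the same branches of length(b) / R(b), where the
  branch range R(b) is the number of cells holding at least one descendant
  of b — evolutionary history down-weighted by how widespread it is
* weighted endemism WE = sum over species of 1 / (number of cells holding
  the species)
* MPD = mean patristic distance over unordered distinct pairs in C
* MNTD = mean over species of the distance to its nearest co-occurring
  relative

PE sums over cells to the total tree branch length when every branch has at
least one occupied cell, and WE sums to the species count — both are used as
conservation checks. Pairwise metrics are undefined for single-species cells
and reported as missing, never zero. The Sorensen dissimilarity between
regional floras is provided for region-level comparison.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .gridding import AssemblageGrid, Cell
from .tree import patristic_matrix, tip_labels

__all__ = [
    "faith_pd",
    "branch_ranges",
    "phylogenetic_endemism",
    "weighted_endemism",
    "mpd",
    "mntd",
    "sorensen_matrix",
    "compute_cell_metrics",
    "TreeIndex",
]

METRIC_COLUMNS = ["cell_i", "cell_j", "region", "S", "PD", "PE", "WE",
                  "MPD", "MNTD", "NRI", "NTI", "class"]


class TreeIndex:
    """Precomputed edge paths for fast PD/PE over many species sets.

    Edges are indexed in preorder; ``path_of[tip]`` lists the edge ids on the
    tip's root path. The root edge participates only if it has a length.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        edges = []
        self._edge_index: dict[int, int] = {}
        root = tree.seed_node
        if root.edge.length:
            edges.append(root.edge)
            self._edge_index[id(root.edge)] = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise ValueError("tree has absent branch lengths; date it first")
            self._edge_index[id(node.edge)] = len(edges)
            edges.append(node.edge)
        self.lengths = np.array([e.length or 0.0 for e in edges], dtype=float)
        self.path_of: dict[str, np.ndarray] = {}
        for leaf in tree.leaf_node_iter():
            ids = []
            node = leaf
            while node.parent_node is not None:
                ids.append(self._edge_index[id(node.edge)])
                node = node.parent_node
            if id(node.edge) in self._edge_index:  # root edge with length
                ids.append(self._edge_index[id(node.edge)])
            self.path_of[leaf.taxon.label] = np.array(sorted(ids), dtype=np.intp)
        self.n_edges = len(edges)
        self._root_path: np.ndarray | None = None

    def spanning_edges(self, species: Iterable[str], include_root: bool = True) -> np.ndarray:
        """Edge ids of the minimal subtree spanning ``species`` (+ root path)."""
        species = list(species)
        if not species:
            raise ValueError("species set is empty")
        missing = [s for s in species if s not in self.path_of]
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        mask = np.zeros(self.n_edges, dtype=bool)
        for s in species:
            mask[self.path_of[s]] = True
        if not include_root:
            # drop edges shared by every selected tip (the MRCA-to-root path)
            shared = np.ones(self.n_edges, dtype=bool)
            for s in species:
                m = np.zeros(self.n_edges, dtype=bool)
                m[self.path_of[s]] = True
                shared &= m
            mask &= ~shared
        return np.flatnonzero(mask)


def faith_pd(tree: dendropy.Tree, species: Iterable[str],
             include_root: bool = True, _index: TreeIndex | None = None) -> float:
    """Faith's phylogenetic diversity of a species set.

    Sum of branch lengths of the minimal spanning subtree; the path from the
    set's MRCA up to the root is included unless ``include_root=False``.
    """
    idx = _index or TreeIndex(tree)
    edges = idx.spanning_edges(species, include_root=include_root)
    return float(idx.lengths[edges].sum())


def branch_ranges(tree: dendropy.Tree, grid: AssemblageGrid,
                  _index: TreeIndex | None = None) -> np.ndarray:
    """R(b) per edge: number of cells containing >=1 descendant of the edge.

    Indexed like :class:`TreeIndex` edges. Edges with no occupied descendant
    cell get R = 0 (they then contribute nothing to PE).
    """
    idx = _index or TreeIndex(tree)
    counts = np.zeros(idx.n_edges, dtype=np.int64)
    for sp_set in grid.cells.values():
        mask = np.zeros(idx.n_edges, dtype=bool)
        for s in sp_set:
            mask[idx.path_of[s]] = True
        counts += mask
    return counts


def phylogenetic_endemism(tree: dendropy.Tree, grid: AssemblageGrid, cell: Cell,
                          _index: TreeIndex | None = None,
                          _ranges: np.ndarray | None = None) -> float:
    """Rosauer's PE for one cell: sum over spanning branches of length/R(b)."""
    if cell not in grid.cells:
        raise KeyError(f"cell {cell} not in grid")
    idx = _index or TreeIndex(tree)
    R = _ranges if _ranges is not None else branch_ranges(tree, grid, _index=idx)
    edges = idx.spanning_edges(grid.cells[cell])
    return float((idx.lengths[edges] / R[edges]).sum())


def weighted_endemism(grid: AssemblageGrid, cell: Cell,
                      _ranges: Mapping[str, int] | None = None) -> float:
    """Weighted endemism: sum over the cell's species of 1/range size."""
    if cell not in grid.cells:
        raise KeyError(f"cell {cell} not in grid")
    ranges = _ranges or species_ranges(grid)
    return float(sum(1.0 / ranges[s] for s in grid.cells[cell]))


def species_ranges(grid: AssemblageGrid) -> dict[str, int]:
    """Number of cells occupied by each species."""
    out: dict[str, int] = {}
    for sp_set in grid.cells.values():
        for s in sp_set:
            out[s] = out.get(s, 0) + 1
    return out


def mpd(dist: pd.DataFrame, species: Iterable[str]) -> float:
    """Mean patristic distance over unordered distinct pairs (presence-weighted)."""
    labels = sorted(set(species))
    if len(labels) < 2:
        raise ValueError("MPD requires at least two species")
    sub = dist.loc[labels, labels].to_numpy()
    iu = np.triu_indices(len(labels), k=1)
    return float(sub[iu].mean())


def mntd(dist: pd.DataFrame, species: Iterable[str]) -> float:
    """Mean distance to the nearest co-occurring taxon."""
    labels = sorted(set(species))
    if len(labels) < 2:
        raise ValueError("MNTD requires at least two species")
    sub = dist.loc[labels, labels].to_numpy(copy=True)
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def sorensen_matrix(pools: Mapping[str, frozenset[str] | set[str]]) -> pd.DataFrame:
    """Pairwise Sorensen dissimilarity between regional floras.

    D(r, s) = 1 - 2|P(r) ∩ P(s)| / (|P(r)| + |P(s)|); zero diagonal.
    """
    if len(pools) < 2:
        raise ValueError("need at least two regions")
    labels = sorted(pools)
    D = np.zeros((len(labels), len(labels)))
    for a, ra in enumerate(labels):
        for b in range(a + 1, len(labels)):
            pa, pb = set(pools[ra]), set(pools[labels[b]])
            d = 1.0 - 2.0 * len(pa & pb) / (len(pa) + len(pb))
            D[a, b] = D[b, a] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def compute_cell_metrics(grid: AssemblageGrid, tree: dendropy.Tree,
                         include_root: bool = True) -> pd.DataFrame:
    """Richness, PD, PE, WE, MPD, MNTD for every cell of the grid.

    NRI/NTI/class columns are present but empty; :mod:`phyloscape.null_models`
    fills them. Single-species cells get missing MPD/MNTD (NaN), not zero.
    All grid species must be tips of the (dated) tree.
    """
    missing = sorted(grid.species - set(tip_labels(tree)))
    if missing:
        raise KeyError(f"grid species absent from tree: {missing}")
    idx = TreeIndex(tree)
    ranges_b = branch_ranges(tree, grid, _index=idx)
    ranges_s = species_ranges(grid)
    dist = patristic_matrix(tree)
    rows = []
    for cell in sorted(grid.cells):
        sp = grid.cells[cell]
        edges = idx.spanning_edges(sp, include_root=include_root)
        row = {
            "cell_i": cell[0],
            "cell_j": cell[1],
            "region": grid.region_of.get(cell, ""),
            "S": len(sp),
            "PD": float(idx.lengths[edges].sum()),
            "PE": float((idx.lengths[edges] / ranges_b[edges]).sum()),
            "WE": float(sum(1.0 / ranges_s[s] for s in sp)),
            "MPD": mpd(dist, sp) if len(sp) >= 2 else np.nan,
            "MNTD": mntd(dist, sp) if len(sp) >= 2 else np.nan,
            "NRI": np.nan,
            "NTI": np.nan,
            "class": "",
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
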