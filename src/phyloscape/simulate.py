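"""Synthetic trees and landscapes for end-to-end pipeline validation.

The generator emulates the statistical structure a continental
spatial-phylogenetic analysis assumes: an ultrametric clade-structured
phylogeny; a rectangular landscape crossed by two orthogonal linear
environmental gradients (moisture along x, temperature along y); species
niche optima evolved along the tree with tunable phylogenetic signal;
assemblages formed under three contrasting scenarios; and a partition of the
grid into labelled regions.

Scenarios
---------
``filtering``
    A species occupies a cell iff both environmental deviations from its
    niche optimum are below a tolerance (plus optional noise). With strong
    niche conservatism, co-occurring species are close relatives —
    phylogenetic clustering.
``refugia``
    Background species occupy spatially contiguous ranges (the
    ``cells_per_species`` cells nearest a random centre), so regional floras
    are distinct subsets of the continental flora; a set of maximally
    distant lineages is confined to designated refugial blocks. Refugial
    cells mix distant lineages — phylogenetic evenness and concentrated
    endemism.
``neutral``
    Every species occupies a fixed number of cells uniformly at random; by
    symmetry, cell composition given richness is a uniform draw from the
    pool, so standardized structure scores should be calibrated (≈5%
    significant at |z| >= 1.96).

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` streams (tree, niche-moisture, niche-temp,
occupancy), so a scenario is bit-reproducible from its config alone.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .gridding import Cell
from .tree import patristic_matrix

__all__ = [
    "ScenarioConfig",
    "simulate_tree",
    "evolve_niche",
    "assemble_occurrences",
    "simulate_scenario",
    "synthetic_taxonomy",
    "landscape_environment",
]

ROOT_AGE = 100.0


@dataclass(frozen=True)
class RegionBlock:
    """Axis-aligned block of cells [i0, i1) x [j0, j1) carrying one label."""
    label: str
    i0: int
    i1: int
    j0: int
    j1: int

    def contains(self, cell: Cell) -> bool:
        return self.i0 <= cell[0] < self.i1 and self.j0 <= cell[1] < self.j1


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic landscape.

    Defaults give a 20 x 20 grid of 10 km cells, 200 species, and a
    filtering tolerance tuned so median cell richness sits around 20 —
    large enough for stable pairwise metrics, small enough that full
    null-model runs stay fast.
    """

    n_species: int = 200
    n_cells_x: int = 20
    n_cells_y: int = 20
    cell_size: float = 10_000.0
    niche_signal: float = 1.0       # 0 = no phylogenetic signal, 1 = pure Brownian
    tolerance: float = 0.16         # niche breadth on the [0,1] gradient scale
    occupancy_noise: float = 0.0    # widens tolerance by U(0, noise) per species-cell
    cells_per_species: int = 40     # neutral/background occupancy (richness ~ n*k/cells)
    refugia: list[tuple[int, int, int, int]] = field(default_factory=list)  # (i0,i1,j0,j1)
    refugium_lineage_count: int = 12
    regions: list[RegionBlock] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_cells_x < 1 or self.n_cells_y < 1 or self.cell_size <= 0:
            raise ValueError("landscape dimensions must be positive")
        if not (0.0 <= self.niche_signal <= 1.0):
            raise ValueError("niche_signal must lie in [0, 1]")
        if not self.regions:
            half = max(1, self.n_cells_x // 2)
            self.regions = [
                RegionBlock("west", 0, half, 0, self.n_cells_y),
                RegionBlock("east", half, self.n_cells_x, 0, self.n_cells_y),
            ]
        for (i0, i1, j0, j1) in self.refugia:
            if not (0 <= i0 < i1 <= self.n_cells_x and 0 <= j0 < j1 <= self.n_cells_y):
                raise ValueError(f"refugium block {(i0, i1, j0, j1)} outside the grid")
        for cell in self._all_cells():
            if sum(r.contains(cell) for r in self.regions) != 1:
                raise ValueError(f"regions must cover every cell exactly once; {cell} fails")

    def _all_cells(self) -> list[Cell]:
        return [(i, j) for i in range(self.n_cells_x) for j in range(self.n_cells_y)]

    def region_of(self, cell: Cell) -> str:
        for r in self.regions:
            if r.contains(cell):
                return r.label
        raise KeyError(cell)

    def _streams(self) -> dict[str, np.random.SeedSequence]:
        root = np.random.SeedSequence(self.seed)
        names = ("tree", "niche_moisture", "niche_temp", "occupancy")
        return dict(zip(names, root.spawn(len(names))))


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree, root age rescaled to 100 units.

    Tips are labelled sp0001, sp0002, ... in leaf order. The same seed
    always yields the same Newick string.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    seed_int = int(np.random.SeedSequence(seed).generate_state(1)[0])
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species,
        rng=_random.Random(seed_int),
    )
    # the simulator stops exactly at the n-th birth, leaving the newest
    # sister pair with zero-length tips; run the clock one further waiting
    # interval (Exp with rate n*lambda) so all terminal branches are positive
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    extra = float(rng.exponential(1.0 / n_species))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra

    def _depth(leaf):
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    height = max(_depth(lf) for lf in tree.leaf_node_iter())
    scale = ROOT_AGE / height
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale
    tree.seed_node.edge.length = None
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{k:04d}"
    for node in tree.preorder_internal_node_iter():
        node.label = None
        if node.taxon is not None:
            node.taxon = None
    tree.update_taxon_namespace()
    return tree


def _brownian_tips(tree: dendropy.Tree, rng: np.random.Generator) -> dict[str, float]:
    """One Brownian trait realized along the tree; value per tip label."""
    value: dict[int, float] = {id(tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            bl = node.edge.length or 0.0
            value[id(node)] = value[id(node.parent_node)] + rng.normal(0.0, np.sqrt(bl))
        if node.is_leaf():
            out[node.taxon.label] = value[id(node)]
    return out


def _rescale01(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def evolve_niche(tree: dendropy.Tree, niche_signal: float, seed: int) -> pd.DataFrame:
    """Niche optima per species on the two [0,1] gradients.

    Each optimum is a mixture ``signal * BM + (1 - signal) * iid uniform``,
    with the Brownian component rescaled to [0,1]. ``niche_signal=0`` makes
    optima independent of the tree; ``=1`` gives pure phylogenetic
    conservatism. Returns a DataFrame indexed by species with columns
    moisture_opt, temp_opt.
    """
    if not (0.0 <= niche_signal <= 1.0):
        raise ValueError("niche_signal must lie in [0, 1]")
    ss = np.random.SeedSequence(seed).spawn(2)
    cols = {}
    for name, child in zip(("moisture_opt", "temp_opt"), ss):
        rng = np.random.default_rng(child)
        bm = _brownian_tips(tree, rng)
        labels = sorted(bm)
        bm01 = _rescale01(np.array([bm[l] for l in labels]))
        unif = rng.uniform(size=len(labels))
        cols[name] = pd.Series(niche_signal * bm01 + (1.0 - niche_signal) * unif,
                               index=labels)
    return pd.DataFrame(cols)


def landscape_environment(config: ScenarioConfig) -> pd.DataFrame:
    """Cell-centre environments: moisture rises along x, temperature along y."""
    rows = []
    for i in range(config.n_cells_x):
        for j in range(config.n_cells_y):
            rows.append({
                "cell_i": i, "cell_j": j,
                "moisture": (i + 0.5) / config.n_cells_x,
                "temp": (j + 0.5) / config.n_cells_y,
            })
    return pd.DataFrame(rows)


def _distant_lineages(tree: dendropy.Tree, count: int) -> list[str]:
    """Greedy max-min selection of maximally distant tips on the tree."""
    D = patristic_matrix(tree)
    labels = list(D.index)
    M = D.to_numpy()
    i, j = np.unravel_index(np.argmax(M), M.shape)
    chosen = [int(i), int(j)]
    while len(chosen) < min(count, len(labels)):
        mind = M[:, chosen].min(axis=1)
        mind[chosen] = -1.0
        chosen.append(int(np.argmax(mind)))
    return sorted(labels[k] for k in chosen)


def _cell_xy(cell: Cell, config: ScenarioConfig, rng: np.random.Generator) -> tuple[float, float]:
    """A point placed uniformly inside the cell (records are points, not cells)."""
    x = (cell[0] + rng.uniform()) * config.cell_size
    y = (cell[1] + rng.uniform()) * config.cell_size
    return x, y


def assemble_occurrences(config: ScenarioConfig, tree: dendropy.Tree,
                         optima: pd.DataFrame, scenario: str = "filtering",
                         ) -> pd.DataFrame:
    """Build an occurrence table for one scenario.

    Returns a DataFrame with columns species, x, y, region (one record per
    occupied species-cell pair; coordinates uniform within the cell). Every
    species is guaranteed at least one record: a species whose rule selects
    no cell is assigned its nearest-environment cell (filtering) or one
    random cell (neutral background).
    """
    if scenario not in ("filtering", "refugia", "neutral"):
        raise ValueError(f"unknown scenario {scenario!r}")
    streams = config._streams()
    rng = np.random.default_rng(streams["occupancy"])
    env = landscape_environment(config)
    cells = list(zip(env.cell_i, env.cell_j))
    moisture = env.moisture.to_numpy()
    temp = env.temp.to_numpy()
    species = sorted(optima.index)

    refuge_cells = [c for c in cells
                    if any(i0 <= c[0] < i1 and j0 <= c[1] < j1
                           for (i0, i1, j0, j1) in config.refugia)]
    if scenario == "refugia" and not refuge_cells:
        raise ValueError("refugia scenario requires at least one refugium block")

    refugial_species: list[str] = []
    if scenario == "refugia":
        refugial_species = _distant_lineages(tree, config.refugium_lineage_count)

    records: list[tuple[str, float, float, str]] = []

    def add(sp: str, cell: Cell):
        x, y = _cell_xy(cell, config, rng)
        records.append((sp, x, y, config.region_of(cell)))

    for sp in species:
        if sp in refugial_species:
            for cell in refuge_cells:
                add(sp, cell)
            continue
        if scenario == "filtering":
            m_opt = optima.loc[sp, "moisture_opt"]
            t_opt = optima.loc[sp, "temp_opt"]
            dm = np.abs(moisture - m_opt)
            dt = np.abs(temp - t_opt)
            if config.occupancy_noise > 0:
                tol = config.tolerance + rng.uniform(0, config.occupancy_noise, size=len(cells))
            else:
                tol = np.full(len(cells), config.tolerance)
            occupied = np.flatnonzero((dm < tol) & (dt < tol))
            if occupied.size == 0:
                occupied = np.array([int(np.argmin(np.maximum(dm, dt)))])
            for k in occupied:
                add(sp, cells[k])
        elif scenario == "neutral":
            k = min(config.cells_per_species, len(cells))
            for idx in rng.choice(len(cells), size=k, replace=False):
                add(sp, cells[idx])
        else:
            # refugia background: contiguous range around a random centre,
            # excluding refugial blocks (refugia are floristically distinct
            # islands — the background flora does not penetrate them)
            open_cells = [c for c in cells if c not in set(refuge_cells)]
            k = min(config.cells_per_species, len(open_cells))
            ci = rng.integers(config.n_cells_x)
            cj = rng.integers(config.n_cells_y)
            d2 = [((c[0] - ci) ** 2 + (c[1] - cj) ** 2, c) for c in open_cells]
            d2.sort()
            for _, cell in d2[:k]:
                add(sp, cell)

    df = pd.DataFrame(records, columns=["species", "x", "y", "region"])
    return df.sort_values(["species", "x", "y"], kind="mergesort").reset_index(drop=True)


def simulate_scenario(config: ScenarioConfig, scenario: str = "filtering",
                      ) -> tuple[dendropy.Tree, pd.DataFrame, pd.DataFrame]:
    """Tree + niche optima + occurrence table for one scenario, from one seed.

    Convenience wrapper chaining :func:`simulate_tree`, :func:`evolve_niche`
    and :func:`assemble_occurrences` on the config's named seed streams.
    """
    streams = config._streams()
    tree_seed = int(streams["tree"].generate_state(1)[0] % 2**31)
    niche_seed = int(streams["niche_moisture"].generate_state(1)[0] % 2**31)
    tree = simulate_tree(config.n_species, tree_seed)
    optima = evolve_niche(tree, config.niche_signal, niche_seed)
    occ = assemble_occurrences(config, tree, optima, scenario)
    return tree, optima, occ


def synthetic_taxonomy(tree: dendropy.Tree, seed: int,
                       genus_age: float = 20.0, family_age: float = 60.0,
                       climbing_fraction: float = 0.2) -> pd.DataFrame:
    """Taxonomy table derived from tree structure.

    Genera are the clades subtended by the first edge crossing ``genus_age``
    on each root-to-tip path; families likewise at ``family_age`` — so
    genera are monophyletic by construction, matching the grafting
    assumption. Growth forms are assigned at random (default 20% climbing).
    Returns columns species, genus, family, growth_form (species as index
    order of tips).
    """
    from .tree import node_ages

    ages = node_ages(tree)
    genus_id: dict[int, int] = {}
    family_id: dict[int, int] = {}

    def crossing_ancestor(leaf, threshold):
        node = leaf
        while node.parent_node is not None and ages[node.parent_node] <= threshold:
            node = node.parent_node
        return node

    rows = []
    g_counter: dict[int, int] = {}
    f_counter: dict[int, int] = {}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    leaves = list(tree.leaf_node_iter())
    forms = np.where(rng.uniform(size=len(leaves)) < climbing_fraction,
                     "climbing", "freestanding")
    for leaf, form in zip(leaves, forms):
        g_node = crossing_ancestor(leaf, genus_age)
        f_node = crossing_ancestor(leaf, family_age)
        g = g_counter.setdefault(id(g_node), len(g_counter) + 1)
        f = f_counter.setdefault(id(f_node), len(f_counter) + 1)
        rows.append({
            "species": leaf.taxon.label,
            "genus": f"genus{g:03d}",
            "family": f"family{f:02d}",
            "growth_form": str(form),
        })
    return pd.DataFrame(rows, columns=["species", "genus", "family", "growth_form"])
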