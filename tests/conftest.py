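"""Shared fixtures: small hand-checkable trees and random tree/grid factories."""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pytest
from dendropy.simulate import treesim

from phyloscape import AssemblageGrid, read_newick


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1)ab:1,C:2)r — the worked example used throughout."""
    return read_newick("((A:1,B:1)ab:1,C:2)r;")


def random_tree(n_tips: int, seed: int, jitter: bool = True) -> dendropy.Tree:
    """Random birth-death topology; branch lengths optionally jittered so the
    tree is not ultrametric (the general case for metric tests)."""
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{k:03d}"
    for node in tree.preorder_internal_node_iter():
        node.label = None
        node.taxon = None
    tree.seed_node.edge.length = None
    if jitter:
        rng = np.random.default_rng(seed)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = float(rng.uniform(0.1, 3.0))
    tree.update_taxon_namespace()
    return tree


def random_grid(labels: list[str], n_cells: int, seed: int,
                min_cell_size: int = 1) -> AssemblageGrid:
    """Random assemblages: every cell gets a nonempty random species subset
    and every species occurs somewhere."""
    rng = np.random.default_rng(seed)
    cells: dict[tuple[int, int], frozenset[str]] = {}
    for c in range(n_cells):
        size = int(rng.integers(min_cell_size, len(labels) + 1))
        chosen = rng.choice(labels, size=size, replace=False)
        cells[(c % 5, c // 5)] = frozenset(str(s) for s in chosen)
    # guarantee full coverage so conservation sums close
    covered = set().union(*cells.values())
    missing = [s for s in labels if s not in covered]
    if missing:
        first = next(iter(cells))
        cells[first] = cells[first] | frozenset(missing)
    regions = {cell: ("north" if cell[1] >= 2 else "south") for cell in cells}
    return AssemblageGrid(cell_size=1.0, cells=cells, region_of=regions)
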