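"""Independent brute-force oracles for metric and null-model tests.

Everything here recomputes quantities from first principles — explicit path
enumeration, edge-by-edge subtree membership, full combination enumeration —
deliberately avoiding the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

import dendropy


def ancestor_edges(leaf: dendropy.Node) -> list[dendropy.Edge]:
    """Edges on the path from a leaf up to (and excluding) the root edge."""
    out = []
    node = leaf
    while node.parent_node is not None:
        out.append(node.edge)
        node = node.parent_node
    return out


def leaf_by_label(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {l.taxon.label: l for l in tree.leaf_node_iter()}


def patristic_bruteforce(tree: dendropy.Tree, a: str, b: str) -> float:
    """Path length between two tips via symmetric difference of root paths."""
    leaves = leaf_by_label(tree)
    ea = {id(e): e for e in ancestor_edges(leaves[a])}
    eb = {id(e): e for e in ancestor_edges(leaves[b])}
    sym = [e for k, e in ea.items() if k not in eb] + [e for k, e in eb.items() if k not in ea]
    return sum(e.length for e in sym)


def subtree_leafsets(tree: dendropy.Tree) -> list[tuple[dendropy.Edge, frozenset[str]]]:
    """(edge, labels of leaves below the edge) for every non-root edge,
    plus the root edge if it carries a length."""
    out = []
    for node in tree.postorder_node_iter():
        labels = frozenset(
            l.taxon.label for l in
            (node.leaf_iter() if not node.is_leaf() else [node])
        )
        if node.parent_node is not None or node.edge.length:
            out.append((node.edge, labels))
    return out


def pd_bruteforce(tree: dendropy.Tree, species: set[str], include_root: bool = True) -> float:
    """Faith PD by edge-wise subtree membership."""
    species = frozenset(species)
    total = 0.0
    for edge, below in subtree_leafsets(tree):
        hit = below & species
        if not hit:
            continue
        if not include_root and hit == species:
            continue  # edge on the shared MRCA-to-root path
        total += edge.length or 0.0
    return total


def branch_ranges_bruteforce(tree: dendropy.Tree, cells: dict) -> dict[int, int]:
    """R(b) per edge id by looping cells x edges."""
    out = {}
    for edge, below in subtree_leafsets(tree):
        out[id(edge)] = sum(1 for sp in cells.values() if below & sp)
    return out


def pe_bruteforce(tree: dendropy.Tree, cells: dict, cell) -> float:
    """Rosauer PE: length/R summed over the cell's spanning edges."""
    R = branch_ranges_bruteforce(tree, cells)
    species = frozenset(cells[cell])
    total = 0.0
    for edge, below in subtree_leafsets(tree):
        if below & species:
            total += (edge.length or 0.0) / R[id(edge)]
    return total


def we_bruteforce(cells: dict, cell) -> float:
    """Weighted endemism by explicit range counting."""
    total = 0.0
    for sp in cells[cell]:
        rng = sum(1 for s in cells.values() if sp in s)
        total += 1.0 / rng
    return total


def mpd_bruteforce(tree: dendropy.Tree, species: set[str]) -> float:
    pairs = list(itertools.combinations(sorted(species), 2))
    return sum(patristic_bruteforce(tree, a, b) for a, b in pairs) / len(pairs)


def mntd_bruteforce(tree: dendropy.Tree, species: set[str]) -> float:
    species = sorted(species)
    total = 0.0
    for a in species:
        total += min(patristic_bruteforce(tree, a, b) for b in species if b != a)
    return total / len(species)


def exhaustive_null_z(tree: dendropy.Tree, pool: set[str], obs: float, S: int) -> float:
    """Negated z-score of obs against the complete C(N, S) MPD enumeration
    (sample SD)."""
    scores = [mpd_bruteforce(tree, set(c)) for c in itertools.combinations(sorted(pool), S)]
    n = len(scores)
    mean = sum(scores) / n
    var = sum((s - mean) ** 2 for s in scores) / (n - 1)
    return -(obs - mean) / math.sqrt(var)
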