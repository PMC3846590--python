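"""Phylogeny container and basic tree operations.

Trees are held as :class:`dendropy.Tree` objects (rooted, labelled tips,
optional branch lengths). This module wraps the handful of operations the
spatial pipeline needs: Newick I/O with stable label handling, pruning to a
species subset while preserving the root, patristic distance matrices, and
total branch length.

Conventions
-----------
* Tip labels are taken from taxon labels; underscores are preserved verbatim.
* A missing branch length is stored as ``None`` ("absent"), never coerced to
  zero. The root edge defaults to length 0 where a number is required.
* Pruning keeps the original root: the root-to-MRCA path is collapsed into a
  single root edge whose length is the path sum, so root-inclusive
  phylogenetic diversity is stable across prunes.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickParseError",
    "read_newick",
    "write_newick",
    "tip_labels",
    "prune_to_species",
    "patristic_matrix",
    "total_branch_length",
    "node_ages",
    "is_ultrametric",
]


class NewickParseError(ValueError):
    """Malformed Newick input; carries the 1-based line/column of the fault."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        super().__init__(message)


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Branch lengths are optional; absent lengths stay ``None``. Internal node
    labels are kept (they carry genus/family names in grafting backbones).

    Raises
    ------
    NewickParseError
        If the string is malformed; the message names the line and column
        where parsing failed.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        where = f" (line {line}, column {col})" if line is not None else ""
        raise NewickParseError(f"malformed Newick{where}: {exc}", line, col) from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick.

    Round-trip safe: ``read_newick(write_newick(t))`` preserves topology,
    labels and branch lengths. Length fields are omitted for edges whose
    length is absent.
    """
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_leaf_taxon_labels=False,
        suppress_internal_node_labels=False,
    ).strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _label_of(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def prune_to_species(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Prune the tree down to ``keep``, retaining the original root.

    Unary internal nodes created by the prune are collapsed, summing branch
    lengths, except that the root node itself is always kept: if the pruned
    root has a single child the chain below it is merged into one root-child
    edge. Patristic distances among kept tips are unchanged.

    Raises
    ------
    KeyError
        If ``keep`` contains labels that are not tips of the tree; the
        message lists the offenders.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must contain at least one species")
    present = set(tip_labels(tree))
    missing = sorted(keep - present)
    if missing:
        raise KeyError(f"species not in tree: {missing}")

    pruned = tree.clone(depth=1)
    # drop unwanted leaves, then collapse unary nodes bottom-up
    changed = True
    while changed:
        changed = False
        for leaf in list(pruned.leaf_node_iter()):
            lbl = _label_of(leaf)
            if lbl not in keep:
                leaf.parent_node.remove_child(leaf)
                changed = True
    for node in list(pruned.postorder_node_iter()):
        if node is pruned.seed_node:
            continue
        if len(node.child_nodes()) == 1:
            child = node.child_nodes()[0]
            parent = node.parent_node
            if node.edge.length is not None or child.edge.length is not None:
                child.edge.length = (node.edge.length or 0.0) + (child.edge.length or 0.0)
            parent.remove_child(node)
            parent.add_child(child)
    pruned.update_taxon_namespace()
    return pruned


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise path-length distances between all tips.

    Returns a symmetric DataFrame indexed by tip label with zero diagonal.
    d(i, j) = depth(i) + depth(j) - 2 * depth(MRCA(i, j)), computed from
    root-path edge membership. All branch lengths must be present (the root
    edge may be absent; it cancels and is ignored).
    """
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    edges = [nd.edge for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    for e in edges:
        if e.length is None:
            raise ValueError(
                f"branch length absent on edge above node "
                f"{_label_of(e.head_node) or '<anonymous>'}; date or assign lengths first"
            )
    eindex = {id(e): i for i, e in enumerate(edges)}
    lengths = np.array([e.length for e in edges], dtype=float)
    # membership matrix: tips x edges on the root path
    M = np.zeros((len(leaves), len(edges)))
    for ti, leaf in enumerate(leaves):
        node = leaf
        while node.parent_node is not None:
            M[ti, eindex[id(node.edge)]] = 1.0
            node = node.parent_node
    depths = M @ lengths
    shared = (M * lengths) @ M.T
    D = depths[:, None] + depths[None, :] - 2.0 * shared
    np.fill_diagonal(D, 0.0)
    D[D < 0] = 0.0  # clip float noise
    return pd.DataFrame(D, index=labels, columns=labels)


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths, including a positive root edge if present."""
    total = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            if node.edge.length:
                total += node.edge.length
        elif node.edge.length is not None:
            total += node.edge.length
    return total


def node_ages(tree: dendropy.Tree) -> Mapping[dendropy.Node, float]:
    """Age of every node = max root-to-tip depth minus node depth.

    Only meaningful for ultrametric trees; used by diagnostics and tests.
    """
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    height = max(depths[l] for l in tree.leaf_node_iter())
    return {n: height - d for n, d in depths.items()}


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    """True if all root-to-tip path sums agree within ``tol``."""
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return (max(depths) - min(depths)) <= tol
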