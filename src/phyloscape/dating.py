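"""Landmark-based age interpolation (bladj-style) producing ultrametric trees.

Given a topology and a table of fixed crown ages for labelled clades, every
undated internal node is assigned an age by even interpolation between its
nearest dated ancestor and a dated node (or tip, age 0) below it. Branch
lengths are then recomputed as parent-age minus child-age, yielding an
ultrametric tree in the units of the age table (Myr by convention).

The processing rule follows the classic branch-length-adjustment scheme:
dated nodes are processed oldest first; when a dated node of age ``tA`` has an
undated descendant chain ending at a dated anchor of age ``tD`` with ``m``
intervening undated nodes, the k-th intervening node receives

    age_k = tA - k * (tA - tD) / (m + 1)

Once a node is dated it is never revised, and newly interpolated nodes act as
anchors for the branches hanging off the chain. The lower anchor of each
chain is the *oldest* dated node in the subtree (ties broken by path length,
then label): this guarantees every interpolated age exceeds every dated age
beneath it, so the output never has negative branch lengths even when a side
branch carries an older landmark than the closest dated node.
"""

from __future__ import annotations

import heapq
import itertools
from typing import Mapping

import dendropy

from .tree import _label_of

__all__ = ["AgeTableError", "read_age_table", "bladj_date"]


class AgeTableError(ValueError):
    """Inconsistent landmark ages (missing root, inverted ancestor order...)."""


def read_age_table(text: str) -> dict[str, float]:
    """Parse a two-column ``clade_label<TAB>age`` table (Myr, positive).

    Blank lines and ``#`` comments are ignored. Duplicate labels or
    non-positive ages raise :class:`AgeTableError`.
    """
    ages: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise AgeTableError(f"line {lineno}: expected 'label<TAB>age', got {raw!r}")
        label, age_s = parts
        if label in ages:
            raise AgeTableError(f"line {lineno}: duplicate clade label {label!r}")
        try:
            age = float(age_s)
        except ValueError as exc:
            raise AgeTableError(f"line {lineno}: bad age {age_s!r}") from exc
        if age <= 0:
            raise AgeTableError(f"line {lineno}: age must be positive, got {age}")
        ages[label] = age
    return ages


def bladj_date(tree: dendropy.Tree, ages: Mapping[str, float]) -> dendropy.Tree:
    """Date a tree from landmark clade ages and return the ultrametric result.

    Parameters
    ----------
    tree
        Rooted tree; internal nodes whose label appears in ``ages`` become
        fixed-age landmarks. The root must be a landmark. Tips are implicitly
        age 0.
    ages
        ``clade_label -> age`` in Myr.

    Raises
    ------
    AgeTableError
        If the root has no fixed age, or a fixed descendant is at least as
        old as its nearest fixed ancestor (both nodes are named).
    """
    dated = tree.clone(depth=1)
    age_of: dict[int, float] = {}  # id(node) -> age
    fixed: dict[int, str] = {}

    for node in dated.preorder_node_iter():
        if node.is_leaf():
            age_of[id(node)] = 0.0
            lbl = _label_of(node)
            if lbl in ages:
                # tip landmark would contradict age-0 tips
                raise AgeTableError(f"landmark {lbl!r} is a tip; tips are fixed at age 0")
        else:
            lbl = _label_of(node)
            if lbl is not None and lbl in ages:
                age_of[id(node)] = float(ages[lbl])
                fixed[id(node)] = lbl

    root = dated.seed_node
    if id(root) not in age_of:
        raise AgeTableError("root age is not fixed: add the root's clade label to the age table")

    # consistency: every fixed node strictly younger than its nearest fixed ancestor
    for node in dated.preorder_node_iter():
        if id(node) not in fixed:
            continue
        anc = node.parent_node
        while anc is not None and id(anc) not in fixed:
            anc = anc.parent_node
        if anc is not None and age_of[id(node)] >= age_of[id(anc)]:
            raise AgeTableError(
                f"fixed node {fixed[id(node)]!r} (age {age_of[id(node)]}) is not younger "
                f"than its fixed ancestor {fixed[id(anc)]!r} (age {age_of[id(anc)]})"
            )

    # oldest-first queue of dated nodes; counter breaks age ties deterministically
    counter = itertools.count()
    heap: list[tuple[float, int, int]] = []
    nodes_by_id = {id(n): n for n in dated.preorder_node_iter()}
    for nid, age in age_of.items():
        node = nodes_by_id[nid]
        if not node.is_leaf():
            heapq.heappush(heap, (-age, next(counter), nid))

    def oldest_dated_below(start: dendropy.Node) -> dendropy.Node:
        """Oldest dated node in the subtree (ties -> fewest edges, then label).

        Anchoring the chain on the oldest dated descendant keeps every
        interpolated age above every dated age below it, so branch lengths
        stay non-negative even when side branches carry older landmarks than
        the closest dated node. BFS stops at dated nodes: anything beneath
        one is necessarily younger.
        """
        best: tuple[float, int, str] | None = None
        best_node: dendropy.Node | None = None
        frontier = [(start, 0)]
        while frontier:
            nxt = []
            for node, depth in frontier:
                if id(node) in age_of:
                    key = (-age_of[id(node)], depth, _label_of(node) or "")
                    if best is None or key < best:
                        best, best_node = key, node
                else:
                    nxt.extend((c, depth + 1) for c in node.child_nodes())
            frontier = nxt
        if best_node is None:  # pragma: no cover - tips are always dated
            raise AgeTableError("undated subtree with no dated descendant")
        return best_node

    while heap:
        _, _, nid = heapq.heappop(heap)
        anchor = nodes_by_id[nid]
        t_a = age_of[nid]
        for child in anchor.child_nodes():
            if id(child) in age_of:
                continue
            below = oldest_dated_below(child)
            t_d = age_of[id(below)]
            # path anchor -> below; the undated run starts at child
            path = []
            node = below
            while node is not child:
                node = node.parent_node
                path.append(node)
            path.reverse()  # child ... parent(below), all undated
            m = len(path)
            for k, node in enumerate(path, start=1):
                age_k = t_a - k * (t_a - t_d) / (m + 1)
                age_of[id(node)] = age_k
                heapq.heappush(heap, (-age_k, next(counter), id(node)))

    # branch lengths = age differences; root edge cleared
    for node in dated.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = age_of[id(node.parent_node)] - age_of[id(node)]
    return dated
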