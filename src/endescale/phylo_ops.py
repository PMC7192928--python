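"""Ultrametric tree handling: Newick I/O, time-depth slicing, clade
collapse with range union (taxonomic lumping), and posterior-set medians.

Node ages are distances to the present (tips at age 0).  Slicing a tree
at age ``depth`` collapses every maximal clade whose crown node is
strictly younger than ``depth``; a node exactly at the slice age is not
collapsed.  Depths at or above the root age collapse the whole tree to a
single unit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .errors import NewickParseError, NotUltrametricError
from .grid_comm import CommunityMatrix

__all__ = [
    "Phylogeny",
    "LumpingResult",
    "read_newick",
    "write_newick",
    "get_clades",
    "collapse_at_depth",
    "summarize_over_trees",
]

#: joiner used for labels of lumped tips
LUMP_SEP = "|"


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


class Phylogeny:
    """A rooted tree with branch lengths in Myr, validated ultrametric.

    Wraps a :class:`dendropy.Tree`.  Validation computes node depths from
    the root, requires every non-root branch to carry a non-negative
    length, unique tip labels, and all tip depths equal within
    ``ultrametric_tol`` (default 1e-6 Myr).  With
    ``require_ultrametric=False`` near-ultrametric trees are accepted and
    node ages are measured against the mean tip depth.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        ultrametric_tol: float = 1e-6,
        require_ultrametric: bool = True,
    ) -> None:
        self._tree = tree
        root = tree.seed_node
        depth: dict[dendropy.Node, float] = {root: 0.0}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            el = node.edge.length
            if el is None:
                raise NewickParseError("branch without a length")
            if el < 0:
                raise ValueError(f"negative branch length {el}")
            depth[node] = depth[node.parent_node] + el
        leaves = list(tree.leaf_node_iter())
        labels = []
        for leaf in leaves:
            if leaf.taxon is None or leaf.taxon.label is None:
                raise NewickParseError("tip without a label")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        tip_depths = np.array([depth[leaf] for leaf in leaves])
        spread = float(tip_depths.max() - tip_depths.min()) if len(leaves) > 1 else 0.0
        if require_ultrametric and spread > ultrametric_tol:
            raise NotUltrametricError(
                f"tip depths span {spread:.3g} Myr (> tolerance {ultrametric_tol:g})"
            )
        self._root_height = float(tip_depths.mean())
        self._age = {
            node: max(self._root_height - d, 0.0) if node.is_leaf() else self._root_height - d
            for node, d in depth.items()
        }
        self._tip_labels = labels

    # -- basic accessors -------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def root_height(self) -> float:
        return self._root_height

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def age(self, node: dendropy.Node) -> float:
        """Node age in Myr (distance to the present)."""
        return self._age[node]

    def total_length(self) -> float:
        """Sum of branch lengths over all non-root branches, in Myr."""
        return sum(
            node.edge.length for node in self._tree.preorder_node_iter() if node.parent_node
        )

    def leaf_label(self, node: dendropy.Node) -> str:
        return node.taxon.label

    def tip_sets(self) -> dict[dendropy.Node, frozenset[str]]:
        """Descendant tip-label set per node (postorder union)."""
        out: dict[dendropy.Node, frozenset[str]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                out[node] = frozenset([node.taxon.label])
            else:
                s: set[str] = set()
                for child in node.child_nodes():
                    s |= out[child]
                out[node] = frozenset(s)
        return out

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | os.PathLike, **kwargs) -> "Phylogeny":
        """Parse a Newick string, or a path to a single-tree Newick file."""
        text = source
        if isinstance(source, os.PathLike) or (
            isinstance(source, str) and "(" not in source and os.path.exists(source)
        ):
            with open(source) as fh:
                text = fh.read()
        try:
            tree = dendropy.Tree.get(
                data=str(text), schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree, **kwargs)

    def to_newick(self) -> str:
        """Serialize with full float precision (round-trips to 1e-9)."""

        def emit(node: dendropy.Node) -> str:
            if node.is_leaf():
                core = node.taxon.label
            else:
                core = "(" + ",".join(emit(c) for c in node.child_nodes()) + ")"
            if node.parent_node is None:
                return core
            return f"{core}:{_fmt(node.edge.length)}"

        return emit(self.root) + ";"

    def prune_to(self, labels: Sequence[str]) -> "Phylogeny":
        """Restrict the tree to the given tips, keeping the original root.

        Unifurcations created by pruning are merged (edge lengths summed),
        so root-to-tip depths — and hence the root height — are preserved.
        """
        keep = set(labels)
        missing = keep - set(self._tip_labels)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        if not keep:
            raise ValueError("cannot prune to an empty tip set")

        def rec(node: dendropy.Node) -> tuple[str, float] | None:
            if node.is_leaf():
                return (node.taxon.label, 0.0) if node.taxon.label in keep else None
            parts = []
            singles = []
            for child in node.child_nodes():
                res = rec(child)
                if res is None:
                    continue
                core, extra = res
                singles.append((core, child.edge.length + extra))
                parts.append(f"{core}:{_fmt(child.edge.length + extra)}")
            if not parts:
                return None
            if len(parts) == 1:
                return singles[0]  # merge unifurcation upward
            return ("(" + ",".join(parts) + ")", 0.0)

        res = rec(self.root)
        if res is None:
            raise ValueError("no kept tips under the root")
        core, extra = res
        if self.root.is_leaf():
            newick = f"({core}:{_fmt(self._root_height)});"
        elif extra > 0 or not core.startswith("("):
            # root collapsed to a single lineage: keep the stem as root edge
            newick = f"({core}:{_fmt(extra)});"
        else:
            newick = core + ";"
        return Phylogeny.from_newick(newick)


@dataclass
class LumpingResult:
    """Outcome of collapsing a tree and community at one time depth."""

    depth: float
    lumped_tree: Phylogeny
    lumped_comm: CommunityMatrix
    tip_map: dict[str, str]


def read_newick(source: str | os.PathLike, **kwargs) -> Phylogeny:
    return Phylogeny.from_newick(source, **kwargs)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def get_clades(tree: Phylogeny, depth: float) -> list[frozenset[str]]:
    """Partition of tips induced by slicing the tree at age ``depth``.

    Each returned set is the tip set of a maximal clade whose crown node
    is strictly younger than ``depth`` (tips count as age-0 clades); the
    sets are disjoint and cover all tips.  ``depth >= root height``
    yields a single set of all tips.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    tips = tree.tip_sets()
    if depth >= tree.root_height:
        return [tips[tree.root]]
    groups: list[frozenset[str]] = []

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            if child.is_leaf() or tree.age(child) < depth:
                groups.append(tips[child])
            else:
                walk(child)

    if tree.root.is_leaf():
        return [tips[tree.root]]
    walk(tree.root)
    return groups


def _lump_label(tip_set: frozenset[str]) -> str:
    return LUMP_SEP.join(sorted(tip_set))


def collapse_at_depth(
    tree: Phylogeny, comm: CommunityMatrix, depth: float
) -> LumpingResult:
    """Merge every clade younger than ``depth`` into one tip, union ranges.

    The lumped tip's subtending branch is extended to the present, so the
    lumped tree is ultrametric with the original root height.  Lumped
    presence is the OR over member tips; the grid is unchanged.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    tree_set = set(tree.tip_labels)
    comm_set = set(comm.taxa)
    if tree_set != comm_set:
        only_tree = sorted(tree_set - comm_set)
        only_comm = sorted(comm_set - tree_set)
        raise ValueError(
            f"tree/community label mismatch: only in tree {only_tree}, "
            f"only in community {only_comm}"
        )
    tips = tree.tip_sets()
    groups = get_clades(tree, depth)

    if len(groups) == 1 and len(groups[0]) == tree.n_tips and depth >= tree.root_height:
        newick = f"({_lump_label(groups[0])}:{_fmt(tree.root_height)});"
    else:

        def emit(node: dendropy.Node) -> str:
            parts = []
            for child in node.child_nodes():
                if child.is_leaf() or tree.age(child) < depth:
                    # collapsed clade: pendant branch spans parent age -> present
                    parts.append(f"{_lump_label(tips[child])}:{_fmt(tree.age(node))}")
                else:
                    parts.append(f"({emit(child)}):{_fmt(child.edge.length)}")
            return ",".join(parts)

        newick = f"({emit(tree.root)});"
    lumped_tree = Phylogeny.from_newick(newick)

    tip_map = {t: _lump_label(g) for g in groups for t in g}
    idx = comm.taxon_index()
    labels = [_lump_label(g) for g in groups]
    presence = np.zeros((comm.grid.n_cells, len(groups)), dtype=bool)
    for j, g in enumerate(groups):
        cols = [idx[t] for t in g]
        presence[:, j] = comm.presence[:, cols].any(axis=1)
    lumped_comm = CommunityMatrix(comm.grid, labels, presence)
    return LumpingResult(depth=depth, lumped_tree=lumped_tree, lumped_comm=lumped_comm, tip_map=tip_map)


def summarize_over_trees(surfaces: Sequence["object"]) -> "object":
    """Per-cell median over a posterior set of endemism surfaces.

    With an even count the midpoint of the two central values is used.
    All surfaces must share one grid and metric.
    """
    from .endemism import EndemismSurface

    if not surfaces:
        raise ValueError("need at least one surface")
    first = surfaces[0]
    for s in surfaces[1:]:
        if s.grid != first.grid:
            raise ValueError("surfaces computed on different grids")
        if s.metric != first.metric:
            raise ValueError("surfaces carry different metrics")
    stack = np.stack([s.values for s in surfaces])
    occ = np.stack([s.occupied for s in surfaces]).any(axis=0)
    return EndemismSurface(
        grid=first.grid,
        metric=first.metric,
        values=np.median(stack, axis=0),
        occupied=occ,
        config=first.config,
    )
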