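"""Shared fixtures and independent oracle implementations.

Oracles here deliberately re-derive quantities by brute force (set
enumeration, root-path walks, sort-and-cut) so they stay independent of
the vectorized code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from endescale import CommunityMatrix, Grid, Phylogeny, simulate_yule_tree


@pytest.fixture
def grid5() -> Grid:
    return Grid(5, 5, grain=1.0)


@pytest.fixture
def grid10() -> Grid:
    return Grid(10, 10, grain=50.0)


def random_community(
    rng: np.random.Generator,
    grid: Grid,
    n_taxa: int,
    p: float = 0.3,
    taxa: list[str] | None = None,
) -> CommunityMatrix:
    """Random presence matrix; every taxon guaranteed >= 1 cell."""
    presence = rng.random((grid.n_cells, n_taxa)) < p
    for j in range(n_taxa):
        if not presence[:, j].any():
            presence[int(rng.integers(grid.n_cells)), j] = True
    labels = taxa if taxa is not None else [f"t{j + 1}" for j in range(n_taxa)]
    return CommunityMatrix(grid, labels, presence)


def random_tree(rng: np.random.Generator, n_tips: int, birth_rate: float = 1.0) -> Phylogeny:
    return simulate_yule_tree(n_tips, birth_rate, seed=int(rng.integers(2**31 - 1)))


# ---------------------------------------------------------------------------
# oracles


def brute_we(comm: CommunityMatrix) -> np.ndarray:
    """Per-taxon 1/R tally, cell by cell."""
    ranges = {
        t: {c for c in range(comm.grid.n_cells) if comm.presence[c, j]}
        for j, t in enumerate(comm.taxa)
    }
    out = np.zeros(comm.grid.n_cells)
    for cell in range(comm.grid.n_cells):
        out[cell] = sum(1.0 / len(cells) for cells in ranges.values() if cell in cells)
    return out


def brute_pe(comm: CommunityMatrix, phy: Phylogeny, proportional: bool = True) -> np.ndarray:
    """Root-path enumeration per cell with independently unioned clade ranges."""
    ranges = {
        t: {c for c in range(comm.grid.n_cells) if comm.presence[c, j]}
        for j, t in enumerate(comm.taxa)
    }
    tree = phy.tree
    total = sum(n.edge.length for n in tree.preorder_node_iter() if n.parent_node)
    leaf_nodes = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    out = np.zeros(comm.grid.n_cells)
    for cell in range(comm.grid.n_cells):
        resident = [t for t in leaf_nodes if cell in ranges[t]]
        branches = set()
        for t in resident:
            node = leaf_nodes[t]
            while node.parent_node is not None:
                branches.add(node)
                node = node.parent_node
        val = 0.0
        for node in branches:
            desc = [lf.taxon.label for lf in node.leaf_iter()]
            clade_cells = set().union(*(ranges[d] for d in desc))
            length = node.edge.length / total if proportional else node.edge.length
            val += length / len(clade_cells)
        out[cell] = val
    return out


def brute_block_or(presence: np.ndarray, n_rows: int, n_cols: int, factor: int) -> np.ndarray:
    """Per coarse cell, explicit OR over its factor x factor fine block."""
    cr, cc = n_rows // factor, n_cols // factor
    n_taxa = presence.shape[1]
    out = np.zeros((cr * cc, n_taxa), dtype=bool)
    for r in range(cr):
        for c in range(cc):
            acc = np.zeros(n_taxa, dtype=bool)
            for dr in range(factor):
                for dc in range(factor):
                    acc |= presence[(r * factor + dr) * n_cols + (c * factor + dc)]
            out[r * cc + c] = acc
    return out


def oracle_quantile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile from first principles."""
    s = sorted(float(v) for v in values)
    n = len(s)
    if n == 1:
        return s[0]
    h = (n - 1) * q
    lo = math.floor(h)
    if lo >= n - 1:
        return s[-1]
    return s[lo] + (h - lo) * (s[lo + 1] - s[lo])


def oracle_hotspots(values: np.ndarray, occupied: np.ndarray, prob: float) -> set[int]:
    """Sort-and-cut with the include-all-ties rule."""
    occ_vals = values[occupied]
    thr = oracle_quantile(occ_vals, 1.0 - prob / 100.0)
    return {c for c in np.flatnonzero(occupied) if values[c] >= thr}


def oracle_autocov(
    values: np.ndarray, grid: Grid, order: int, weighting: str
) -> np.ndarray:
    """Brute-force neighbour enumeration with explicit offsets."""
    offsets = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    if order == 2:
        offsets += [(1, 1), (1, -1), (-1, 1), (-1, -1), (2, 0), (-2, 0), (0, 2), (0, -2)]
    out = np.zeros(grid.n_cells)
    for cell in range(grid.n_cells):
        r, c = divmod(cell, grid.n_cols)
        num = den = 0.0
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols):
                continue
            w = 1.0 if weighting == "equal" else 1.0 / (math.hypot(dr, dc) * grid.grain)
            num += w * values[rr * grid.n_cols + cc]
            den += w
        out[cell] = num / den if den > 0 else 0.0
    return out


def is_connected(cells: set[int], grid: Grid) -> bool:
    """Graph-traversal connectivity check on rook adjacency."""
    if not cells:
        return False
    seen = set()
    stack = [next(iter(cells))]
    while stack:
        c = stack.pop()
        if c in seen:
            continue
        seen.add(c)
        r, cc = divmod(c, grid.n_cols)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, c2 = r + dr, cc + dc
            nb = rr * grid.n_cols + c2
            if 0 <= rr < grid.n_rows and 0 <= c2 < grid.n_cols and nb in cells:
                stack.append(nb)
    return seen == cells
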