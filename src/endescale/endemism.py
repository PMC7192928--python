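"""Weighted endemism (WE) and phylogenetic endemism (PE) surfaces.

WE(cell) = sum over resident taxa of r_t / R_t, with ranges counted in
grid cells; with the default focal-cell neighbourhood r_t = 1.

PE(cell) = sum over branches on the root paths of the cell's residents
of L_i / R_i, each branch counted once; L_i is the branch length as a
proportion of total tree length (a raw-Myr switch is provided) and R_i
is the cell count of the union of the branch's descendant tip ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

import dendropy

from .grid_comm import CommunityMatrix, Grid
from .phylo_ops import Phylogeny

__all__ = [
    "ScaleConfig",
    "EndemismSurface",
    "weighted_endemism",
    "branch_ranges",
    "phylo_endemism",
    "restrict_extent",
]


@dataclass(frozen=True)
class ScaleConfig:
    """One point in the (grain, extent, lumping depth, threshold) design."""

    grain: float
    extent: str = "global"
    lump_depth: float = 0.0
    hotspot_prob: float = 2.5

    def __post_init__(self) -> None:
        if not (0 < self.hotspot_prob < 50):
            raise ValueError("hotspot_prob must lie in (0, 50) percent")
        if self.lump_depth < 0:
            raise ValueError("lump_depth must be non-negative")


@dataclass
class EndemismSurface:
    """Per-cell values of one endemism metric for one scale configuration."""

    grid: Grid
    metric: str
    values: np.ndarray = field(repr=False)
    occupied: np.ndarray = field(repr=False)
    config: Optional[ScaleConfig] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.values.shape != (self.grid.n_cells,):
            raise ValueError("values must hold one entry per grid cell")
        if self.values.min(initial=0.0) < 0:
            raise ValueError("endemism values must be non-negative")


def weighted_endemism(comm: CommunityMatrix, radius: int = 0) -> EndemismSurface:
    """WE per cell: richness inversely weighted by global range size.

    ``radius`` sets the Chebyshev radius of the local neighbourhood used
    for the local range r_t; the default 0 uses the focal cell alone
    (r_t = 1 for each resident taxon), matching per-cell endemism maps.
    """
    R = comm.range_sizes().astype(float)
    if radius == 0:
        values = comm.presence @ (1.0 / R)
    else:
        grid = comm.grid
        cube = comm.presence.reshape(grid.n_rows, grid.n_cols, comm.n_taxa).astype(float)
        # windowed sum over a (2r+1)^2 Chebyshev neighbourhood, zero-padded
        pad = np.zeros(
            (grid.n_rows + 2 * radius, grid.n_cols + 2 * radius, comm.n_taxa)
        )
        pad[radius : radius + grid.n_rows, radius : radius + grid.n_cols] = cube
        csum = pad.cumsum(axis=0).cumsum(axis=1)
        z = np.zeros((csum.shape[0] + 1, csum.shape[1] + 1, comm.n_taxa))
        z[1:, 1:] = csum
        w = 2 * radius + 1
        r0 = np.arange(grid.n_rows)
        c0 = np.arange(grid.n_cols)
        local = (
            z[np.ix_(r0 + w, c0 + w)]
            - z[np.ix_(r0, c0 + w)]
            - z[np.ix_(r0 + w, c0)]
            + z[np.ix_(r0, c0)]
        )
        values = (local.reshape(grid.n_cells, comm.n_taxa) @ (1.0 / R))
    return EndemismSurface(
        grid=comm.grid, metric="WE", values=values, occupied=comm.occupied()
    )


def _branch_table(
    comm: CommunityMatrix, tree: Phylogeny
) -> tuple[np.ndarray, np.ndarray, list[frozenset[str]]]:
    """Descendant-tip indicator matrix and raw lengths per non-root branch.

    Returns (D, L, tip_sets): D is (n_branches, n_taxa) over the *community's*
    taxon ordering; L holds raw branch lengths in Myr.
    """
    tree_tips = set(tree.tip_labels)
    comm_tips = set(comm.taxa)
    missing = sorted(tree_tips - comm_tips)
    if missing:
        raise ValueError(f"tree tips absent from community: {missing}")
    extra = sorted(comm_tips - tree_tips)
    if extra:
        warnings.warn(
            f"community taxa absent from tree ignored for PE: {extra}", stacklevel=3
        )
    idx = comm.taxon_index()
    desc: dict[dendropy.Node, np.ndarray] = {}
    rows: list[np.ndarray] = []
    lengths: list[float] = []
    sets: list[frozenset[str]] = []
    labels = tree.tip_sets()
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(comm.n_taxa, dtype=bool)
            v[idx[node.taxon.label]] = True
        else:
            v = np.zeros(comm.n_taxa, dtype=bool)
            for child in node.child_nodes():
                v |= desc[child]
        desc[node] = v
        if node.parent_node is not None:  # root's subtending branch excluded
            rows.append(v)
            lengths.append(float(node.edge.length))
            sets.append(labels[node])
    return np.array(rows), np.array(lengths), sets


def branch_ranges(comm: CommunityMatrix, tree: Phylogeny) -> dict[frozenset[str], int]:
    """R_i per branch: cells occupied by the union of descendant tip ranges.

    Branches are keyed by their descendant tip-label sets (unique in a
    tree without unifurcations).
    """
    D, _, sets = _branch_table(comm, tree)
    branch_cells = (comm.presence.astype(np.uint8) @ D.T.astype(np.uint8)) > 0
    R = branch_cells.sum(axis=0)
    return {s: int(r) for s, r in zip(sets, R)}


def phylo_endemism(
    comm: CommunityMatrix, tree: Phylogeny, proportional: bool = True
) -> EndemismSurface:
    """PE per cell; see module docstring for the exact form.

    With ``proportional=True`` (default) branch lengths enter as
    proportions of total tree length, so PE sums to 1 over cells when all
    tips are sampled.  ``proportional=False`` uses raw Myr.
    """
    D, L, _ = _branch_table(comm, tree)
    branch_cells = (comm.presence.astype(np.uint8) @ D.T.astype(np.uint8)) > 0
    R = branch_cells.sum(axis=0).astype(float)
    if proportional:
        total = L.sum()
        if total <= 0:
            raise ValueError("tree has zero total branch length")
        L = L / total
    values = branch_cells.astype(float) @ (L / R)
    return EndemismSurface(
        grid=comm.grid, metric="PE", values=values, occupied=comm.occupied()
    )


def restrict_extent(
    comm: CommunityMatrix, regions: "RegionLabels", extent: str
) -> CommunityMatrix:
    """Truncate the community to one region; ranges become regional.

    ``extent`` is a continent or country label from ``regions`` (or
    "global", a no-op).  Cells outside the region lose all presences,
    taxa left with none are dropped, and R_t is implicitly recomputed
    within the region; PE on the result is regional PE.
    """
    if extent == "global":
        return comm
    cont = np.asarray(regions.continent)
    ctry = np.asarray(regions.country)
    if extent in cont:
        mask = cont == extent
    elif extent in ctry:
        mask = ctry == extent
    else:
        raise ValueError(f"unknown region label {extent!r}")
    if mask.shape != (comm.grid.n_cells,):
        raise ValueError("region labels do not match the community grid")
    presence = comm.presence.copy()
    presence[~mask, :] = False
    keep = presence.any(axis=0)
    dropped = [t for t, k in zip(comm.taxa, keep) if not k]
    if dropped:
        warnings.warn(
            f"{len(dropped)} taxa absent from extent {extent!r} dropped", stacklevel=2
        )
    taxa = [t for t, k in zip(comm.taxa, keep) if k]
    if not taxa:
        raise ValueError(f"no taxa present within extent {extent!r}")
    return CommunityMatrix(comm.grid, taxa, presence[:, keep])
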