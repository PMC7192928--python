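"""Equal-area grids and binary presence-absence community matrices.

Cells are indexed 0-based, row-major from the south-west corner: cell
``i`` sits at row ``i // n_cols`` (row 0 is the southernmost) and column
``i % n_cols``.  Coordinates are abstract planar kilometres in an
equal-area frame, so every cell of one grid shares the same area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptyCommunityError

__all__ = [
    "Grid",
    "CommunityMatrix",
    "ranges_to_community",
    "aggregate_grain",
    "species_richness",
]

#: taxon -> set of cell ids (or a shapely geometry awaiting rasterization)
RangeSet = Mapping[str, object]


@dataclass(frozen=True)
class Grid:
    """A regular lattice of square equal-area cells.

    Parameters
    ----------
    n_rows, n_cols
        Lattice shape; row 0 is the southernmost row.
    grain
        Cell edge length in km.  ``cell_area`` is ``grain ** 2``.
    origin
        Planar (x, y) of the grid's south-west corner, in km.
    """

    n_rows: int
    n_cols: int
    grain: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.grain <= 0:
            raise ValueError("grain must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        return self.grain * self.grain

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def rowcol(self, cell: int) -> tuple[int, int]:
        return divmod(int(cell), self.n_cols)

    def cell_at(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of planar centroid coordinates in km."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x = self.origin[0] + (cols + 0.5) * self.grain
        y = self.origin[1] + (rows + 0.5) * self.grain
        return np.column_stack([x, y])

    # rook offsets for neighbourhood orders 1 and 2 (order 2 = cells at
    # rook-graph distance <= 2: adds diagonals and two-step straights)
    _ORDER1 = ((1, 0), (-1, 0), (0, 1), (0, -1))
    _ORDER2_EXTRA = ((1, 1), (1, -1), (-1, 1), (-1, -1), (2, 0), (-2, 0), (0, 2), (0, -2))

    def neighbor_offsets(self, order: int = 1) -> tuple[tuple[int, int], ...]:
        if order == 1:
            return self._ORDER1
        if order == 2:
            return self._ORDER1 + self._ORDER2_EXTRA
        raise ValueError(f"neighbour order must be 1 or 2, got {order}")

    def rook_neighbors(self, cell: int) -> list[int]:
        """The (up to 4) rook-adjacent cell ids of ``cell``."""
        r, c = self.rowcol(cell)
        out = []
        for dr, dc in self._ORDER1:
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                out.append(self.cell_at(rr, cc))
        return out

    def neighbors(self, cell: int, order: int = 1) -> list[int]:
        r, c = self.rowcol(cell)
        out = []
        for dr, dc in self.neighbor_offsets(order):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                out.append(self.cell_at(rr, cc))
        return out

    def coarsen(self, factor: int) -> tuple["Grid", np.ndarray]:
        """Aggregate ``factor x factor`` blocks of cells into coarse cells.

        Trailing rows/columns beyond the largest divisible block are
        dropped (mapped to -1) with a warning, keeping coarse cells
        equal-area.

        Returns
        -------
        coarse : Grid
        fine_to_coarse : ndarray of int
            Per fine cell, the coarse cell id, or -1 for dropped cells.
        """
        if factor < 2:
            raise ValueError("aggregation factor must be >= 2")
        keep_rows = (self.n_rows // factor) * factor
        keep_cols = (self.n_cols // factor) * factor
        if keep_rows == 0 or keep_cols == 0:
            raise ValueError(f"grid {self.n_rows}x{self.n_cols} too small for factor {factor}")
        if keep_rows != self.n_rows or keep_cols != self.n_cols:
            warnings.warn(
                f"grid {self.n_rows}x{self.n_cols} not divisible by {factor}; "
                f"dropping trailing cells beyond {keep_rows}x{keep_cols}",
                stacklevel=2,
            )
        coarse = Grid(
            n_rows=keep_rows // factor,
            n_cols=keep_cols // factor,
            grain=self.grain * factor,
            origin=self.origin,
        )
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        mapping = np.full(self.n_cells, -1, dtype=int)
        inside = (rows < keep_rows) & (cols < keep_cols)
        mapping[inside] = (rows[inside] // factor) * coarse.n_cols + cols[inside] // factor
        return coarse, mapping


@dataclass
class CommunityMatrix:
    """Binary presence of taxa in grid cells.

    ``presence[cell, j]`` is True iff taxon ``taxa[j]`` occupies the cell.
    Every retained taxon occupies at least one cell (R_t >= 1).
    """

    grid: Grid
    taxa: list[str]
    presence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (self.grid.n_cells, len(self.taxa)):
            raise ValueError(
                f"presence shape {self.presence.shape} does not match "
                f"({self.grid.n_cells} cells, {len(self.taxa)} taxa)"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels in community matrix")
        ranges = self.presence.sum(axis=0)
        if len(self.taxa) and ranges.min() < 1:
            empty = [t for t, r in zip(self.taxa, ranges) if r == 0]
            raise ValueError(f"taxa with empty ranges: {empty}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def range_sizes(self) -> np.ndarray:
        """R_t per taxon: global range in number of occupied cells."""
        return self.presence.sum(axis=0)

    def richness(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    def occupied(self) -> np.ndarray:
        """Boolean mask of cells holding at least one taxon."""
        return self.presence.any(axis=1)

    def taxon_index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.taxa)}

    def subset_taxa(self, keep: Sequence[str]) -> "CommunityMatrix":
        idx = self.taxon_index()
        cols = [idx[t] for t in keep]
        return CommunityMatrix(self.grid, list(keep), self.presence[:, cols])


def _is_geometry(obj: object) -> bool:
    return hasattr(obj, "geom_type") and hasattr(obj, "contains")


def ranges_to_community(ranges: RangeSet, grid: Grid) -> CommunityMatrix:
    """Build the presence-absence matrix from explicit cell sets or polygons.

    Cell-set ranges are taken verbatim; polygon ranges are rasterized by a
    centroid-in-polygon test.  Taxa whose ranges rasterize empty are
    dropped with a warning; if all do, :class:`EmptyCommunityError` is
    raised.
    """
    if not ranges:
        raise EmptyCommunityError("no taxa supplied")
    taxa: list[str] = []
    columns: list[np.ndarray] = []
    centroids = None
    for taxon, rng in ranges.items():
        col = np.zeros(grid.n_cells, dtype=bool)
        if _is_geometry(rng):
            from shapely import contains_xy

            if centroids is None:
                centroids = grid.centroids()
            col = contains_xy(rng, centroids[:, 0], centroids[:, 1])
        else:
            cells = np.fromiter((int(c) for c in rng), dtype=int, count=len(rng))  # type: ignore[arg-type]
            if cells.size and (cells.min() < 0 or cells.max() >= grid.n_cells):
                bad = cells[(cells < 0) | (cells >= grid.n_cells)]
                raise ValueError(f"taxon {taxon!r} references unknown cell ids {bad.tolist()}")
            col[cells] = True
        if not col.any():
            warnings.warn(f"taxon {taxon!r} has an empty rasterized range; dropped", stacklevel=2)
            continue
        taxa.append(str(taxon))
        columns.append(col)
    if not taxa:
        raise EmptyCommunityError("every taxon rasterized to an empty range")
    return CommunityMatrix(grid, taxa, np.column_stack(columns))


def aggregate_grain(comm: CommunityMatrix, factor: int) -> CommunityMatrix:
    """Coarsen the community by OR-ing presence over factor x factor blocks.

    The coarse grain is ``fine grain * factor``.  On grids not divisible
    by ``factor`` the trailing margin is dropped (warning); taxa left with
    no cells after the drop are removed with a warning.
    """
    grid = comm.grid
    coarse, mapping = grid.coarsen(factor)
    cube = comm.presence.reshape(grid.n_rows, grid.n_cols, comm.n_taxa)
    keep_rows = coarse.n_rows * factor
    keep_cols = coarse.n_cols * factor
    cube = cube[:keep_rows, :keep_cols]
    blocks = cube.reshape(coarse.n_rows, factor, coarse.n_cols, factor, comm.n_taxa)
    coarse_presence = blocks.any(axis=(1, 3)).reshape(coarse.n_cells, comm.n_taxa)
    ranges = coarse_presence.sum(axis=0)
    taxa = comm.taxa
    if len(taxa) and ranges.min() == 0:
        lost = [t for t, r in zip(taxa, ranges) if r == 0]
        warnings.warn(f"taxa confined to the dropped margin removed: {lost}", stacklevel=2)
        keep = ranges > 0
        coarse_presence = coarse_presence[:, keep]
        taxa = [t for t, k in zip(taxa, keep) if k]
    return CommunityMatrix(coarse, list(taxa), coarse_presence)


def species_richness(comm: CommunityMatrix) -> np.ndarray:
    """Per-cell count of resident taxa."""
    return comm.richness()
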