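"""Percentile hotspots of an endemism surface and protected-area coverage.

The threshold for ``prob`` percent is the (100 - prob)th percentile of
the surface over occupied cells (linear-interpolation quantile); every
cell at or above the threshold is a hotspot, so ties may push the
hotspot fraction above ``prob``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .endemism import EndemismSurface, ScaleConfig
from .errors import EmptySurfaceError
from .grid_comm import Grid

__all__ = [
    "HotspotMask",
    "ProtectionLayer",
    "ProtectionReport",
    "hotspots",
    "tiered_hotspots",
    "protection_coverage",
]


@dataclass
class HotspotMask:
    """Cells in the top ``prob`` percent of one endemism surface."""

    grid: Grid
    prob: float
    threshold: float
    cells: np.ndarray = field(repr=False)  # boolean per cell

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())

    def cell_ids(self) -> np.ndarray:
        return np.flatnonzero(self.cells)


@dataclass
class ProtectionLayer:
    """Per-cell fraction of area covered by protected areas, in [0, 1]."""

    grid: Grid
    fraction: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.fraction.shape != (self.grid.n_cells,):
            raise ValueError("fraction must hold one entry per grid cell")
        if self.fraction.min() < 0 or self.fraction.max() > 1:
            raise ValueError("protected fractions must lie in [0, 1]")


@dataclass
class ProtectionReport:
    """How many hotspot cells meet a minimum protected-coverage target."""

    n_hotspot_cells: int
    n_meeting_target: int
    proportion_meeting_target: float
    target: float = 0.10
    config: Optional[ScaleConfig] = None


def hotspots(
    surface: EndemismSurface, prob: float = 2.5, include_empty: bool = False
) -> HotspotMask:
    """Cells whose value reaches the (100 - prob)th percentile.

    Quantiles are computed over occupied cells only (``include_empty``
    switches to all cells); all ties at the threshold are included.
    """
    if not (0 < prob < 50):
        raise ValueError("prob must lie in (0, 50) percent")
    pool = np.ones(surface.grid.n_cells, dtype=bool) if include_empty else surface.occupied
    vals = surface.values[pool]
    if vals.size == 0:
        raise EmptySurfaceError("surface has no occupied cells")
    threshold = float(np.quantile(vals, 1.0 - prob / 100.0))
    cells = pool & (surface.values >= threshold)
    return HotspotMask(grid=surface.grid, prob=prob, threshold=threshold, cells=cells)


def tiered_hotspots(
    surface: EndemismSurface, probs: Sequence[float] = (2.5, 5.0)
) -> np.ndarray:
    """Per-cell tier labels ("none" or "topP" for each prob, tightest wins).

    Because a tighter prob implies an equal-or-higher threshold, tighter
    tiers nest inside looser ones.
    """
    tier = np.full(surface.grid.n_cells, "none", dtype=object)
    for prob in sorted(probs, reverse=True):  # loosest first, tightest overwrites
        mask = hotspots(surface, prob)
        tier[mask.cells] = f"top{prob:g}"
    return tier


def protection_coverage(
    mask: HotspotMask, protection: ProtectionLayer, target: float = 0.10
) -> ProtectionReport:
    """Proportion of hotspot cells whose protected fraction meets ``target``."""
    if mask.grid != protection.grid:
        raise ValueError("hotspot mask and protection layer use different grids")
    if not (0 <= target <= 1):
        raise ValueError("target must lie in [0, 1]")
    hot = mask.cells
    n = int(hot.sum())
    meet = int((protection.fraction[hot] >= target).sum())
    return ProtectionReport(
        n_hotspot_cells=n,
        n_meeting_target=meet,
        proportion_meeting_target=meet / n if n else 0.0,
        target=target,
    )
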