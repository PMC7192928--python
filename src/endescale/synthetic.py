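"""Synthetic worlds: trees, ranges, environments, regions, protection.

Every generator is a pure function of its arguments including ``seed``.
Grid adjacency for contiguity is rook (4-neighbour) throughout; range
sizes follow a truncated log-normal (many small, few large); regions are
grown from seed cells so each is spatially contiguous.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .env_model import LAYER_NAMES, EnvLayerSet
from .grid_comm import Grid
from .hotspots import ProtectionLayer
from .phylo_ops import Phylogeny

__all__ = [
    "RegionLabels",
    "SyntheticWorld",
    "simulate_yule_tree",
    "expected_yule_root_height",
    "simulate_ranges",
    "simulate_environment",
    "partition_regions",
    "simulate_protection",
    "make_world",
    "write_world",
    "read_world",
]


@dataclass
class RegionLabels:
    """Per-cell continent and country labels; countries nest in continents."""

    grid: Grid
    continent: np.ndarray = field(repr=False)
    country: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.continent = np.asarray(self.continent, dtype=object)
        self.country = np.asarray(self.country, dtype=object)
        n = self.grid.n_cells
        if self.continent.shape != (n,) or self.country.shape != (n,):
            raise ValueError("labels must hold one entry per grid cell")

    def continent_labels(self) -> list[str]:
        return sorted(set(self.continent))

    def country_labels(self) -> list[str]:
        return sorted(set(self.country))


@dataclass
class SyntheticWorld:
    """Everything the pipeline needs, generated from one seed."""

    grid: Grid
    trees: list[Phylogeny]
    ranges: dict[str, frozenset[int]]
    env: EnvLayerSet
    regions: RegionLabels
    protection: ProtectionLayer
    seed: int
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        taxa = set(self.ranges)
        for i, tree in enumerate(self.trees):
            if set(tree.tip_labels) != taxa:
                raise ValueError(f"tree {i} tip set differs from range taxa")
        n = self.grid.n_cells
        for t, cells in self.ranges.items():
            if not cells:
                raise ValueError(f"taxon {t!r} has an empty range")
            if any(c < 0 or c >= n for c in cells):
                raise ValueError(f"taxon {t!r} references cells outside the grid")
        if self.env.grid != self.grid or self.regions.grid != self.grid:
            raise ValueError("environment/regions grid mismatch")
        if self.protection.grid != self.grid:
            raise ValueError("protection grid mismatch")


# ---------------------------------------------------------------------------
# trees


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> Phylogeny:
    """Pure-birth tree, forward simulation from two root lineages.

    Starting from 2 lineages, each speciation waits Exp(k * birth_rate);
    after the n-th lineage appears one further Exp(n * birth_rate) hold
    sets the present, so tip branches are never zero.  The expected root
    height is sum_{k=2..n} 1/(k * birth_rate)
    (:func:`expected_yule_root_height`).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    # node records: (birth_time, parent_index); -1 = root child
    birth = [0.0, 0.0]
    parent = [-1, -1]
    children: dict[int, list[int]] = {}
    active = [0, 1]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node = active.pop(i)
        kids = []
        for _ in range(2):
            birth.append(t)
            parent.append(node)
            kids.append(len(birth) - 1)
        children[node] = kids
        active.extend(kids)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    present = t
    labels = [f"t{i + 1}" for i in range(n_tips)]
    order = rng.permutation(n_tips)
    label_of = {tip: labels[order[j]] for j, tip in enumerate(sorted(active))}

    def emit(node: int) -> str:
        if node in children:
            stop = birth[children[node][0]]  # this lineage ends at its split
            core = "(" + ",".join(emit(c) for c in children[node]) + ")"
        else:
            stop = present
            core = label_of[node]
        return f"{core}:{stop - birth[node]:.17g}"

    return Phylogeny.from_newick(f"({emit(0)},{emit(1)});")


def expected_yule_root_height(n_tips: int, birth_rate: float) -> float:
    """Closed-form E[root height] for :func:`simulate_yule_tree`'s variant."""
    return sum(1.0 / (k * birth_rate) for k in range(2, n_tips + 1))


# ---------------------------------------------------------------------------
# ranges


def _spreading_dye(grid: Grid, size: int, rng: np.random.Generator) -> frozenset[int]:
    """Grow a contiguous cell set of ``size`` cells on rook adjacency."""
    start = int(rng.integers(grid.n_cells))
    cells = {start}
    frontier = [c for c in grid.rook_neighbors(start)]
    while len(cells) < size and frontier:
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        cell = frontier.pop()
        if cell in cells:
            continue
        cells.add(cell)
        for nb in grid.rook_neighbors(cell):
            if nb not in cells:
                frontier.append(nb)
    return frozenset(cells)


def simulate_ranges(
    grid: Grid,
    tree: Phylogeny | Sequence[str],
    mean_range: float = 5.0,
    skew: float = 0.8,
    seed: int = 0,
) -> dict[str, frozenset[int]]:
    """Contiguous spreading-dye ranges with log-normal sizes.

    Sizes are log-normal with expectation ``mean_range`` and log-scale SD
    ``skew``, rounded and truncated to [1, n_cells]; each range grows
    from a random seed cell over the rook adjacency graph.
    """
    if grid.n_cells < 1:
        raise ValueError("empty grid")
    if not (1 <= mean_range <= grid.n_cells):
        raise ValueError("mean_range must lie in [1, number of grid cells]")
    if skew < 0:
        raise ValueError("skew must be non-negative")
    taxa = tree.tip_labels if isinstance(tree, Phylogeny) else list(tree)
    rng = np.random.default_rng(seed)
    mu = math.log(mean_range) - skew**2 / 2.0
    raw = rng.lognormal(mean=mu, sigma=skew, size=len(taxa)) if skew > 0 else np.full(len(taxa), mean_range)
    sizes = np.clip(np.rint(raw).astype(int), 1, grid.n_cells)
    return {t: _spreading_dye(grid, int(s), rng) for t, s in zip(taxa, sizes)}


# ---------------------------------------------------------------------------
# environment


def simulate_environment(
    grid: Grid,
    subcells_per_cell: int = 16,
    autocorr_length: float = 2.0,
    seed: int = 0,
) -> EnvLayerSet:
    """Four spatially autocorrelated layers on a subcell lattice.

    Each cell holds a k x k block of subcells (``subcells_per_cell`` must
    be a perfect square >= 4).  Layers are independent smoothed-noise
    fields plus a latitudinal gradient; ``autocorr_length`` (in cell
    widths) sets the Gaussian smoothing scale.  An infinite
    ``autocorr_length`` yields constant layers (zero within-cell SD).
    """
    if subcells_per_cell < 4:
        raise ValueError("need at least 4 subcells per cell")
    k = int(round(math.sqrt(subcells_per_cell)))
    if k * k != subcells_per_cell:
        raise ValueError("subcells_per_cell must be a perfect square")
    rng = np.random.default_rng(seed)
    R, C = grid.n_rows * k, grid.n_cols * k
    # per-layer (gradient strength, offset, scale): loosely climate-like
    layer_params = {
        "temperature": (-1.5, 20.0, 5.0),
        "precipitation": (0.8, 1000.0, 400.0),
        "productivity": (0.6, 0.5, 0.2),
        "elevation": (0.0, 500.0, 300.0),
    }
    lat = np.linspace(-1.0, 1.0, R)[:, None] * np.ones((1, C))
    layers: dict[str, np.ndarray] = {}
    for name in LAYER_NAMES:
        grad_w, offset, scale = layer_params[name]
        if np.isinf(autocorr_length):
            fine = np.full((R, C), offset)
        else:
            from scipy.ndimage import gaussian_filter

            noise = rng.standard_normal((R, C))
            sigma = max(autocorr_length * k, 1e-9)
            smooth = gaussian_filter(noise, sigma=sigma, mode="nearest")
            sd = smooth.std()
            if sd > 0:
                smooth = smooth / sd
            fine = offset + scale * (smooth + grad_w * lat)
        blocks = fine.reshape(grid.n_rows, k, grid.n_cols, k)
        layers[name] = blocks.transpose(0, 2, 1, 3).reshape(grid.n_cells, k * k)
    return EnvLayerSet(grid=grid, k=k, layers=layers)


# ---------------------------------------------------------------------------
# regions


def _grow_partition(
    cells: Sequence[int],
    n_regions: int,
    neighbors: Mapping[int, list[int]],
    rng: np.random.Generator,
) -> dict[int, int]:
    """Contiguous partition by balanced multi-source growth.

    Seeds are drawn at random; at each step the smallest growable region
    claims a random unassigned frontier cell.  Every region stays
    connected because cells attach only to an already-claimed neighbour.
    """
    cells = list(cells)
    assignment: dict[int, int] = {}
    seeds = rng.choice(len(cells), size=n_regions, replace=False)
    frontiers: list[list[int]] = [[] for _ in range(n_regions)]
    sizes = [0] * n_regions
    for r, si in enumerate(seeds):
        c = cells[int(si)]
        assignment[c] = r
        sizes[r] += 1
        frontiers[r].extend(nb for nb in neighbors[c] if nb not in assignment)
    remaining = len(cells) - n_regions
    while remaining > 0:
        growable = [r for r in range(n_regions) if frontiers[r]]
        if not growable:
            break
        r = min(growable, key=lambda r: (sizes[r], r))
        f = frontiers[r]
        claimed = None
        while f:
            i = int(rng.integers(len(f)))
            f[i], f[-1] = f[-1], f[i]
            cand = f.pop()
            if cand not in assignment:
                claimed = cand
                break
        if claimed is None:
            continue
        assignment[claimed] = r
        sizes[r] += 1
        remaining -= 1
        f.extend(nb for nb in neighbors[claimed] if nb not in assignment)
    return assignment


def partition_regions(
    grid: Grid,
    n_continents: int,
    countries_per_continent: int,
    seed: int = 0,
) -> RegionLabels:
    """Nested contiguous continent/country labels grown from seed cells."""
    if n_continents < 1 or countries_per_continent < 1:
        raise ValueError("need at least one continent and one country per continent")
    if n_continents * countries_per_continent > grid.n_cells:
        raise ValueError("more regions than grid cells")
    rng = np.random.default_rng(seed)
    all_nb = {c: grid.rook_neighbors(c) for c in range(grid.n_cells)}
    cont_assign = _grow_partition(range(grid.n_cells), n_continents, all_nb, rng)
    continent = np.empty(grid.n_cells, dtype=object)
    for c, r in cont_assign.items():
        continent[c] = f"C{r + 1}"
    country = np.empty(grid.n_cells, dtype=object)
    for r in range(n_continents):
        members = [c for c in range(grid.n_cells) if cont_assign[c] == r]
        n_countries = min(countries_per_continent, len(members))
        member_set = set(members)
        sub_nb = {c: [nb for nb in all_nb[c] if nb in member_set] for c in members}
        ctry_assign = _grow_partition(members, n_countries, sub_nb, rng)
        for c, s in ctry_assign.items():
            country[c] = f"C{r + 1}-K{s + 1}"
    return RegionLabels(grid=grid, continent=continent, country=country)


# ---------------------------------------------------------------------------
# protection


def simulate_protection(
    grid: Grid,
    mean_coverage: float = 0.15,
    patchiness: float = 2.0,
    seed: int = 0,
) -> ProtectionLayer:
    """Right-skewed per-cell protected fractions with the given mean.

    Fractions are Beta-distributed with mean ``mean_coverage`` and
    concentration 1/``patchiness``; larger patchiness concentrates
    coverage in fewer cells (most cells near zero).
    """
    if not (0 <= mean_coverage <= 1):
        raise ValueError("mean_coverage must lie in [0, 1]")
    if patchiness <= 0:
        raise ValueError("patchiness must be positive")
    rng = np.random.default_rng(seed)
    if mean_coverage == 0:
        frac = np.zeros(grid.n_cells)
    elif mean_coverage == 1:
        frac = np.ones(grid.n_cells)
    else:
        conc = 1.0 / patchiness
        a = mean_coverage * conc
        b = (1.0 - mean_coverage) * conc
        frac = rng.beta(a, b, size=grid.n_cells)
    return ProtectionLayer(grid=grid, fraction=frac)


# ---------------------------------------------------------------------------
# whole worlds


DEFAULT_WORLD = dict(
    n_rows=10,
    n_cols=10,
    grain=50.0,
    n_taxa=30,
    n_trees=10,
    birth_rate=0.3,
    mean_range=6.0,
    skew=0.8,
    subcells_per_cell=16,
    autocorr_length=2.0,
    n_continents=2,
    countries_per_continent=2,
    mean_coverage=0.15,
    patchiness=2.0,
)


def make_world(seed: int = 0, **overrides) -> SyntheticWorld:
    """Generate a complete, cross-consistent synthetic world.

    Keyword overrides replace entries of :data:`DEFAULT_WORLD`.  The
    world is a pure function of ``seed`` and the parameters.
    """
    params = dict(DEFAULT_WORLD)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown world parameters: {sorted(unknown)}")
    params.update(overrides)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=5 + params["n_trees"])]
    grid = Grid(params["n_rows"], params["n_cols"], grain=params["grain"])
    trees = [
        simulate_yule_tree(params["n_taxa"], params["birth_rate"], seed=sub[5 + i])
        for i in range(params["n_trees"])
    ]
    ranges = simulate_ranges(
        grid, trees[0], mean_range=params["mean_range"], skew=params["skew"], seed=sub[0]
    )
    env = simulate_environment(
        grid,
        subcells_per_cell=params["subcells_per_cell"],
        autocorr_length=params["autocorr_length"],
        seed=sub[1],
    )
    regions = partition_regions(
        grid,
        params["n_continents"],
        params["countries_per_continent"],
        seed=sub[2],
    )
    protection = simulate_protection(
        grid,
        mean_coverage=params["mean_coverage"],
        patchiness=params["patchiness"],
        seed=sub[3],
    )
    world = SyntheticWorld(
        grid=grid,
        trees=trees,
        ranges=ranges,
        env=env,
        regions=regions,
        protection=protection,
        seed=seed,
        params=params,
    )
    world.validate()
    return world


# ---------------------------------------------------------------------------
# world bundle I/O (plain-text directory with a manifest)


def write_world(world: SyntheticWorld, outdir: str | os.PathLike) -> None:
    """Write a world to a directory of delimited tables plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "trees.nwk", "w") as fh:
        for tree in world.trees:
            fh.write(tree.to_newick() + "\n")
    rows = [(t, c) for t, cells in world.ranges.items() for c in sorted(cells)]
    pd.DataFrame(rows, columns=["species", "cell"]).to_csv(out / "ranges.csv", index=False)
    env_df = pd.DataFrame(
        {name: arr.ravel() for name, arr in world.env.layers.items()}
    )
    n_sub = world.env.n_subcells
    env_df.insert(0, "subcell", np.tile(np.arange(n_sub), world.grid.n_cells))
    env_df.insert(0, "cell", np.repeat(world.grid.cell_ids, n_sub))
    env_df.to_csv(out / "environment.csv", index=False)
    pd.DataFrame(
        {
            "cell": world.grid.cell_ids,
            "continent": world.regions.continent,
            "country": world.regions.country,
        }
    ).to_csv(out / "regions.csv", index=False)
    pd.DataFrame(
        {"cell": world.grid.cell_ids, "fraction": world.protection.fraction}
    ).to_csv(out / "protection.csv", index=False)
    manifest = {
        "seed": world.seed,
        "params": world.params,
        "grid": {
            "n_rows": world.grid.n_rows,
            "n_cols": world.grid.n_cols,
            "grain": world.grid.grain,
            "origin": list(world.grid.origin),
        },
        "env_k": world.env.k,
        "n_trees": len(world.trees),
        "n_taxa": len(world.ranges),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_world(indir: str | os.PathLike) -> SyntheticWorld:
    """Read a world bundle written by :func:`write_world`."""
    src = Path(indir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    g = manifest["grid"]
    grid = Grid(g["n_rows"], g["n_cols"], grain=g["grain"], origin=tuple(g["origin"]))
    trees = []
    with open(src / "trees.nwk") as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(Phylogeny.from_newick(line))
    rdf = pd.read_csv(src / "ranges.csv")
    ranges: dict[str, frozenset[int]] = {
        t: frozenset(sub["cell"].astype(int)) for t, sub in rdf.groupby("species", sort=False)
    }
    edf = pd.read_csv(src / "environment.csv").sort_values(["cell", "subcell"])
    n_sub = edf["subcell"].max() + 1
    layers = {
        name: edf[name].to_numpy().reshape(grid.n_cells, n_sub) for name in LAYER_NAMES
    }
    env = EnvLayerSet(grid=grid, k=manifest["env_k"], layers=layers)
    gdf = pd.read_csv(src / "regions.csv").sort_values("cell")
    regions = RegionLabels(
        grid=grid,
        continent=gdf["continent"].to_numpy(dtype=object),
        country=gdf["country"].to_numpy(dtype=object),
    )
    pdf = pd.read_csv(src / "protection.csv").sort_values("cell")
    protection = ProtectionLayer(grid=grid, fraction=pdf["fraction"].to_numpy())
    world = SyntheticWorld(
        grid=grid,
        trees=trees,
        ranges=ranges,
        env=env,
        regions=regions,
        protection=protection,
        seed=manifest["seed"],
        params=manifest.get("params", {}),
    )
    world.validate()
    return world
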