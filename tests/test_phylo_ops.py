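import numpy as np
import pytest

from endescale import (
    EndemismSurface,
    Grid,
    NewickParseError,
    NotUltrametricError,
    Phylogeny,
    collapse_at_depth,
    get_clades,
    ranges_to_community,
    read_newick,
    summarize_over_trees,
    weighted_endemism,
    write_newick,
)

from conftest import random_tree

BALANCED = "((A:0.5,B:0.5):1.5,C:2);"


class TestNewickIO:
    def test_basic_parse(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert t.root_height == pytest.approx(2.0)
        assert sorted(t.tip_labels) == ["A", "B", "C"]

    def test_round_trip_many_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = random_tree(rng, int(rng.integers(3, 20)))
            t2 = read_newick(write_newick(t))
            assert t2.root_height == pytest.approx(t.root_height, abs=1e-9)
            assert _topology_key(t) == _topology_key(t2)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(NotUltrametricError):
            read_newick("((A:1,B:1):1,C:3);")

    def test_non_ultrametric_tolerated_with_flag(self):
        t = read_newick("((A:1,B:1):1,C:3);", require_ultrametric=False)
        assert t.root_height == pytest.approx((2 + 2 + 3) / 3)

    def test_malformed_raises_parse_error(self):
        with pytest.raises(NewickParseError):
            read_newick("((A:1,B:1:1,C:2);")

    def test_missing_branch_length_raises(self):
        with pytest.raises(NewickParseError):
            read_newick("((A,B):1,C:2);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_newick("((A:1,A:1):1,C:2);")

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            read_newick("((A:1,B:1):-1,C:0);", require_ultrametric=False)

    def test_file_round_trip(self, tmp_path):
        p = tmp_path / "tree.nwk"
        p.write_text(BALANCED)
        t = read_newick(p)
        assert t.n_tips == 3


def _topology_key(t: Phylogeny):
    sets = t.tip_sets()
    return frozenset(
        (s, round(node.edge.length, 10))
        for node, s in sets.items()
        if node.parent_node is not None
    )


class TestGetClades:
    def test_depth_zero_gives_singletons(self):
        t = read_newick(BALANCED)
        assert sorted(map(sorted, get_clades(t, 0.0))) == [["A"], ["B"], ["C"]]

    def test_depth_at_or_above_root_gives_single_set(self):
        t = read_newick(BALANCED)
        for depth in (t.root_height, t.root_height + 1, 100.0):
            assert get_clades(t, depth) == [frozenset("ABC")]

    def test_hand_enumerated_slice(self):
        # node (A,B) at age 0.5 < 1, so A and B merge; C stays alone
        t = read_newick(BALANCED)
        assert sorted(map(sorted, get_clades(t, 1.0))) == [["A", "B"], ["C"]]

    def test_node_exactly_at_slice_not_collapsed(self):
        t = read_newick(BALANCED)
        assert sorted(map(sorted, get_clades(t, 0.5))) == [["A"], ["B"], ["C"]]

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            get_clades(read_newick(BALANCED), -1.0)

    def test_partition_property_random(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            t = random_tree(rng, int(rng.integers(4, 15)))
            for depth in rng.uniform(0, t.root_height * 1.2, size=5):
                groups = get_clades(t, float(depth))
                tips = [x for g in groups for x in g]
                assert len(tips) == len(set(tips)) == t.n_tips

    def test_monotone_refinement(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = random_tree(rng, 10)
            depths = sorted(rng.uniform(0, t.root_height * 1.1, size=6))
            parts = [get_clades(t, d) for d in depths]
            for fine, coarse in zip(parts, parts[1:]):
                for g in fine:
                    assert any(g <= h for h in coarse)

    def test_group_count_monotone_in_depth(self):
        rng = np.random.default_rng(5)
        t = random_tree(rng, 12)
        depths = np.linspace(0, t.root_height + 0.5, 8)
        counts = [len(get_clades(t, float(d))) for d in depths]
        assert counts[0] == 12 and counts[-1] == 1
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCollapseAtDepth:
    def _comm(self):
        grid = Grid(1, 2)
        return ranges_to_community({"A": {0}, "B": {1}, "C": {0}}, grid)

    def test_depth_zero_is_identity(self):
        t = read_newick(BALANCED)
        res = collapse_at_depth(t, self._comm(), 0.0)
        assert sorted(res.lumped_tree.tip_labels) == ["A", "B", "C"]
        assert res.lumped_tree.root_height == pytest.approx(2.0)
        assert np.array_equal(
            res.lumped_comm.presence.sum(axis=0), self._comm().presence.sum(axis=0)
        )

    def test_hand_constructed_lump(self):
        t = read_newick(BALANCED)
        res = collapse_at_depth(t, self._comm(), 1.0)
        assert sorted(res.lumped_tree.tip_labels) == ["A|B", "C"]
        # A|B pendant branch restored to the present: root age 2.0
        ab = next(
            n for n in res.lumped_tree.tree.leaf_node_iter() if n.taxon.label == "A|B"
        )
        assert ab.edge.length == pytest.approx(2.0)
        j = res.lumped_comm.taxa.index("A|B")
        assert set(np.flatnonzero(res.lumped_comm.presence[:, j])) == {0, 1}
        assert res.tip_map == {"A": "A|B", "B": "A|B", "C": "C"}

    def test_total_collapse_gives_uniform_inverse_range(self):
        t = read_newick(BALANCED)
        comm = self._comm()
        res = collapse_at_depth(t, comm, t.root_height + 1)
        assert res.lumped_tree.n_tips == 1
        we = weighted_endemism(res.lumped_comm)
        # single lumped taxon in both cells: WE = 1/2 in each
        assert we.values.tolist() == [0.5, 0.5]

    def test_label_mismatch_lists_offenders(self):
        t = read_newick(BALANCED)
        grid = Grid(1, 2)
        comm = ranges_to_community({"A": {0}, "B": {1}, "X": {0}}, grid)
        with pytest.raises(ValueError, match="X"):
            collapse_at_depth(t, comm, 1.0)

    def test_preserves_ultrametricity_and_root_height(self):
        rng = np.random.default_rng(9)
        grid = Grid(4, 4)
        for _ in range(20):
            t = random_tree(rng, 10)
            ranges = {
                lbl: {int(rng.integers(grid.n_cells))} for lbl in t.tip_labels
            }
            comm = ranges_to_community(ranges, grid)
            depth = float(rng.uniform(0, t.root_height * 1.1))
            res = collapse_at_depth(t, comm, depth)
            # Phylogeny construction itself enforces ultrametricity (tol 1e-6)
            assert res.lumped_tree.root_height == pytest.approx(t.root_height, abs=1e-6)

    def test_tip_count_non_increasing_in_depth(self):
        rng = np.random.default_rng(10)
        t = random_tree(rng, 15)
        grid = Grid(3, 3)
        ranges = {lbl: {int(rng.integers(9))} for lbl in t.tip_labels}
        comm = ranges_to_community(ranges, grid)
        counts = [
            collapse_at_depth(t, comm, d).lumped_tree.n_tips
            for d in np.linspace(0, t.root_height + 0.1, 6)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPruneTo:
    def test_prune_keeps_root_height(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            t = random_tree(rng, 12)
            keep = list(rng.choice(t.tip_labels, size=5, replace=False))
            p = t.prune_to(keep)
            assert sorted(p.tip_labels) == sorted(keep)
            assert p.root_height == pytest.approx(t.root_height, abs=1e-9)

    def test_prune_to_single_tip(self):
        t = read_newick(BALANCED)
        p = t.prune_to(["A"])
        assert p.tip_labels == ["A"]
        assert p.root_height == pytest.approx(2.0)

    def test_prune_unknown_label(self):
        with pytest.raises(ValueError):
            read_newick(BALANCED).prune_to(["Z"])


class TestSummarizeOverTrees:
    def _surface(self, grid, vals):
        return EndemismSurface(
            grid=grid, metric="WE", values=np.asarray(vals, float),
            occupied=np.asarray(vals) > 0,
        )

    def test_single_surface_identity(self, grid5):
        s = self._surface(grid5, np.arange(25.0))
        out = summarize_over_trees([s])
        assert np.array_equal(out.values, s.values)

    def test_odd_count_median(self):
        g = Grid(1, 1)
        out = summarize_over_trees(
            [self._surface(g, [1.0]), self._surface(g, [5.0]), self._surface(g, [100.0])]
        )
        assert out.values[0] == 5.0

    def test_even_count_midpoint(self):
        g = Grid(1, 1)
        out = summarize_over_trees([self._surface(g, [1.0]), self._surface(g, [2.0])])
        assert out.values[0] == pytest.approx(1.5)

    def test_matches_sort_based_median(self, grid5):
        rng = np.random.default_rng(13)
        surfaces = [self._surface(grid5, rng.random(25)) for _ in range(100)]
        out = summarize_over_trees(surfaces)
        stack = np.stack([s.values for s in surfaces])
        for cell in range(25):
            col = sorted(stack[:, cell])
            expected = (col[49] + col[50]) / 2
            assert out.values[cell] == pytest.approx(expected, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            summarize_over_trees([])

    def test_grid_mismatch_rejected(self, grid5):
        a = self._surface(grid5, np.ones(25))
        b = self._surface(Grid(5, 5, grain=2.0), np.ones(25))
        with pytest.raises(ValueError):
            summarize_over_trees([a, b])
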