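"""Faith PD, Rosauer PE, weighted endemism, MPD/MNTD, Sorensen — against
hand calculations and brute-force enumeration oracles."""

import numpy as np
import pytest

from phyloscape import (
    AssemblageGrid,
    branch_ranges,
    compute_cell_metrics,
    faith_pd,
    mntd,
    mpd,
    patristic_matrix,
    phylogenetic_endemism,
    sorensen_matrix,
    total_branch_length,
    weighted_endemism,
)
from phyloscape.metrics import TreeIndex, species_ranges

from conftest import random_grid, random_tree
from oracles import (
    branch_ranges_bruteforce,
    mntd_bruteforce,
    mpd_bruteforce,
    pd_bruteforce,
    pe_bruteforce,
    we_bruteforce,
)


class TestFaithPD:
    def test_pair_spans_stem_and_root_path(self, three_tip_tree):
        assert faith_pd(three_tip_tree, {"A", "B"}) == pytest.approx(3.0)

    def test_full_set_equals_total_branch_length(self, three_tip_tree):
        assert faith_pd(three_tip_tree, {"A", "B", "C"}) == pytest.approx(
            total_branch_length(three_tip_tree))

    def test_single_species_is_tip_to_root_path(self, three_tip_tree):
        assert faith_pd(three_tip_tree, {"C"}) == pytest.approx(2.0)

    def test_exclude_root_drops_shared_path(self, three_tip_tree):
        assert faith_pd(three_tip_tree, {"A", "B"}, include_root=False) == pytest.approx(2.0)
        assert faith_pd(three_tip_tree, {"C"}, include_root=False) == pytest.approx(0.0)

    def test_empty_set_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            faith_pd(three_tip_tree, set())

    def test_monotone_in_species(self):
        t = random_tree(10, seed=3)
        labels = sorted(l.taxon.label for l in t.leaf_node_iter())
        last = 0.0
        for k in range(1, len(labels) + 1):
            pd_k = faith_pd(t, set(labels[:k]))
            assert pd_k >= last - 1e-12
            last = pd_k


class TestPERosauer:
    def test_two_cells_each_branch_restricted(self, three_tip_tree):
        cells = {(0, 0): frozenset({"A", "B"}), (1, 0): frozenset({"C"})}
        g = AssemblageGrid(cell_size=1.0, cells=cells)
        assert phylogenetic_endemism(three_tip_tree, g, (0, 0)) == pytest.approx(3.0)
        assert phylogenetic_endemism(three_tip_tree, g, (1, 0)) == pytest.approx(2.0)

    def test_ubiquitous_species_contributes_length_over_ncells(self, three_tip_tree):
        cells = {(k, 0): frozenset({"A"}) for k in range(4)}
        g = AssemblageGrid(cell_size=1.0, cells=cells)
        # branches A, ab-stem all have R=4; PE per cell = (1+1)/4
        assert phylogenetic_endemism(three_tip_tree, g, (0, 0)) == pytest.approx(0.5)

    def test_branch_ranges_match_bruteforce(self, three_tip_tree):
        cells = {(0, 0): frozenset({"A", "B"}), (1, 0): frozenset({"B", "C"})}
        g = AssemblageGrid(cell_size=1.0, cells=cells)
        idx = TreeIndex(three_tip_tree)
        got = branch_ranges(three_tip_tree, g, _index=idx)
        oracle = branch_ranges_bruteforce(three_tip_tree, cells)
        # oracle keyed by edge identity, implementation by edge index; the
        # multiset of R values identifies any disagreement on this tree
        assert sorted(got.tolist()) == sorted(oracle.values())


class TestConservation:
    @pytest.mark.parametrize("seed", range(8))
    def test_pe_sums_to_total_length_and_we_to_richness(self, seed):
        t = random_tree(n_tips=8, seed=seed)
        labels = sorted(l.taxon.label for l in t.leaf_node_iter())
        g = random_grid(labels, n_cells=10, seed=seed)
        pe_sum = sum(phylogenetic_endemism(t, g, c) for c in g.cells)
        assert pe_sum == pytest.approx(total_branch_length(t), abs=1e-9)
        we_sum = sum(weighted_endemism(g, c) for c in g.cells)
        assert we_sum == pytest.approx(len(labels), abs=1e-9)


class TestPairwiseMetrics:
    def test_mpd_hand_example(self, three_tip_tree):
        D = patristic_matrix(three_tip_tree)
        assert mpd(D, {"A", "B", "C"}) == pytest.approx(10 / 3)
        assert mpd(D, {"A", "B"}) == pytest.approx(2.0)

    def test_mntd_hand_example(self, three_tip_tree):
        D = patristic_matrix(three_tip_tree)
        assert mntd(D, {"A", "B", "C"}) == pytest.approx(8 / 3)
        assert mntd(D, {"A", "C"}) == pytest.approx(mpd(D, {"A", "C"}))

    def test_single_species_undefined(self, three_tip_tree):
        D = patristic_matrix(three_tip_tree)
        with pytest.raises(ValueError):
            mpd(D, {"A"})
        with pytest.raises(ValueError):
            mntd(D, {"A"})

    @pytest.mark.parametrize("seed", range(8))
    def test_mntd_never_exceeds_mpd(self, seed):
        t = random_tree(n_tips=9, seed=30 + seed)
        D = patristic_matrix(t)
        rng = np.random.default_rng(seed)
        sub = set(rng.choice(D.index, size=5, replace=False))
        assert mntd(D, sub) <= mpd(D, sub) + 1e-12


class TestSorensen:
    def test_identical_pools_zero(self):
        D = sorensen_matrix({"a": {"x", "y"}, "b": {"x", "y"}})
        assert D.loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_pools_one(self):
        D = sorensen_matrix({"a": {"x"}, "b": {"y"}})
        assert D.loc["a", "b"] == pytest.approx(1.0)

    def test_half_overlap(self):
        D = sorensen_matrix({"a": {"A", "B"}, "b": {"B", "C"}})
        assert D.loc["a", "b"] == pytest.approx(0.5)
        assert np.allclose(np.diag(D.to_numpy()), 0.0)

    def test_single_region_rejected(self):
        with pytest.raises(ValueError):
            sorensen_matrix({"a": {"x"}})


class TestAgainstBruteForce:
    """Randomized equivalence with independent enumeration oracles."""

    @pytest.mark.parametrize("seed", range(12))
    def test_all_metrics_match_oracles(self, seed):
        t = random_tree(n_tips=4 + seed % 10, seed=500 + seed)
        labels = sorted(l.taxon.label for l in t.leaf_node_iter())
        g = random_grid(labels, n_cells=6 + seed % 10, seed=seed)
        idx = TreeIndex(t)
        ranges_b = branch_ranges(t, g, _index=idx)
        D = patristic_matrix(t)
        for cell, sp in g.cells.items():
            assert faith_pd(t, sp, _index=idx) == pytest.approx(
                pd_bruteforce(t, sp), abs=1e-9)
            assert faith_pd(t, sp, include_root=False, _index=idx) == pytest.approx(
                pd_bruteforce(t, sp, include_root=False), abs=1e-9)
            assert phylogenetic_endemism(t, g, cell, _index=idx, _ranges=ranges_b) == \
                pytest.approx(pe_bruteforce(t, g.cells, cell), abs=1e-9)
            assert weighted_endemism(g, cell) == pytest.approx(
                we_bruteforce(g.cells, cell), abs=1e-9)
            if len(sp) >= 2:
                assert mpd(D, sp) == pytest.approx(mpd_bruteforce(t, sp), abs=1e-9)
                assert mntd(D, sp) == pytest.approx(mntd_bruteforce(t, sp), abs=1e-9)


class TestCellMetricsTable:
    def test_invariants_hold_per_cell(self):
        t = random_tree(n_tips=10, seed=9, jitter=False)
        labels = sorted(l.taxon.label for l in t.leaf_node_iter())
        g = random_grid(labels, n_cells=8, seed=9)
        m = compute_cell_metrics(g, t)
        assert (m["S"] >= 1).all()
        assert (m["PD"] > 0).all()
        assert (m["PE"] <= m["PD"] + 1e-12).all()
        assert (m["WE"] <= m["S"] + 1e-12).all()
        two_plus = m["S"] >= 2
        assert (m.loc[two_plus, "MNTD"] <= m.loc[two_plus, "MPD"] + 1e-12).all()

    def test_single_species_cell_gets_missing_pairwise(self, three_tip_tree):
        g = AssemblageGrid(cell_size=1.0, cells={
            (0, 0): frozenset({"C"}), (1, 0): frozenset({"A", "B"})})
        m = compute_cell_metrics(g, three_tip_tree).set_index("cell_i")
        assert np.isnan(m.loc[0, "MPD"]) and np.isnan(m.loc[0, "MNTD"])
        assert m.loc[0, "PD"] == pytest.approx(2.0)

    def test_unknown_grid_species_rejected(self, three_tip_tree):
        g = AssemblageGrid(cell_size=1.0, cells={(0, 0): frozenset({"A", "Z"})})
        with pytest.raises(KeyError, match="Z"):
            compute_cell_metrics(g, three_tip_tree)

    def test_species_ranges_counts_cells(self):
        g = AssemblageGrid(cell_size=1.0, cells={
            (0, 0): frozenset({"a", "b"}), (1, 0): frozenset({"a"})})
        assert species_ranges(g) == {"a": 2, "b": 1}
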