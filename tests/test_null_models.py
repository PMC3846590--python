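"""Richness-preserving null draws, convergence rules, NRI/NTI standardization."""

import numpy as np
import pytest

from phyloscape import (
    AssemblageGrid,
    NullModelConfig,
    classify,
    convergence_check,
    draw_null_assemblages,
    mpd,
    patristic_matrix,
    read_newick,
    run_nri_analysis,
    standardize,
)

from oracles import exhaustive_null_z, mpd_bruteforce


class TestDraws:
    def test_pool4_s2_exhausts_all_six_combinations(self):
        draws = draw_null_assemblages({"A", "B", "C", "D"}, 2, max_iter=100, seed=1)
        assert len(draws) == 6
        assert len(set(draws)) == 6
        assert draw_null_assemblages.last_stop_reason == "combinations_exhausted"

    def test_full_pool_is_single_degenerate_draw(self):
        draws = draw_null_assemblages({"A", "B", "C"}, 3, max_iter=100, seed=1)
        assert draws == [frozenset({"A", "B", "C"})]
        assert draw_null_assemblages.last_stop_reason == "degenerate"

    def test_seed_reproduces_sequence(self):
        a = draw_null_assemblages(set("ABCDEFGHIJ"), 3, max_iter=50, seed=9)
        b = draw_null_assemblages(set("ABCDEFGHIJ"), 3, max_iter=50, seed=9)
        assert a == b

    def test_no_combination_reused_in_sampling_regime(self):
        # C(12, 3) = 220 > max_iter so the rejection-sampling path runs
        draws = draw_null_assemblages({f"s{k}" for k in range(12)}, 3,
                                      max_iter=150, seed=2)
        assert len(draws) == 150
        assert len(set(draws)) == 150
        assert draw_null_assemblages.last_stop_reason == "max_iterations"

    def test_richness_above_pool_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            draw_null_assemblages({"A", "B"}, 3, max_iter=10, seed=0)

    def test_draws_are_uniform_over_combinations(self):
        # frequency of each of the 10 C(5,2) pairs over many short sequences
        counts = {}
        for seed in range(300):
            for d in draw_null_assemblages(set("ABCDE"), 2, max_iter=3, seed=seed):
                counts[d] = counts.get(d, 0) + 1
        freqs = np.array(list(counts.values()), dtype=float)
        assert len(counts) == 10
        assert freqs.std() / freqs.mean() < 0.2


class TestConvergence:
    def test_literal_mode_never_fires_for_similar_scores(self):
        scores = [3.0] * 150
        assert not convergence_check(scores, mode="literal")
        assert convergence_check(scores, mode="relative_range")

    def test_literal_mode_fires_on_tiny_min_max_ratio(self):
        scores = [0.001] + [1.0] * 120
        # window covers the last 100 values only
        assert not convergence_check(scores, mode="literal")
        assert convergence_check([1.0] * 30 + [0.0001] + [1.0] * 99,
                                 mode="literal")

    def test_short_history_never_converges(self):
        assert not convergence_check([1.0] * 99, mode="relative_range")

    def test_min_iteration_gate_enforced_by_driver(self):
        # star tree: all pairwise distances equal, so relative_range would
        # fire immediately — but never before min_iter_before_stop draws
        labels = [f"t{k}" for k in range(40)]
        star = read_newick("(" + ",".join(f"{t}:1" for t in labels) + ");")
        # second cell holds every species so the continental pool is all 40
        g = AssemblageGrid(cell_size=1.0, cells={
            (0, 0): frozenset({"t0", "t1"}), (1, 0): frozenset(labels)})
        cfg = NullModelConfig(max_iter=600, min_iter_before_stop=500,
                              convergence_mode="relative_range", seed=4)
        _, audit = run_nri_analysis(g, star, cfg)
        s2 = audit[audit.S == 2]
        assert set(s2["stop_reason"]) == {"converged"}
        assert set(s2["n_draws"]) == {500}
        cfg_lit = NullModelConfig(max_iter=600, min_iter_before_stop=500,
                                  convergence_mode="literal", seed=4)
        _, audit_lit = run_nri_analysis(g, star, cfg_lit)
        s2 = audit_lit[audit_lit.S == 2]
        assert set(s2["stop_reason"]) == {"max_iterations"}
        assert set(s2["n_draws"]) == {600}


class TestStandardize:
    def test_negation_and_sign_convention(self):
        assert standardize(2.0, 10 / 3, 1.1547) == pytest.approx(1.1547, abs=1e-4)
        assert standardize(4.0, 10 / 3, 1.1547) == pytest.approx(-0.5774, abs=1e-4)
        assert standardize(5.0, 5.0, 2.0) == 0.0

    def test_zero_sd_gives_nan(self):
        assert np.isnan(standardize(1.0, 1.0, 0.0))

    @pytest.mark.parametrize("z,expected", [
        (2.5, "clustered_sig"), (1.2, "clustered_weak"), (0.3, "neutral"),
        (-0.99, "neutral"), (-1.2, "even_weak"), (-2.5, "even_sig"),
        (float("nan"), "neutral"),
    ])
    def test_classification_bands(self, z, expected):
        assert classify(z) == expected

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify(1.0, sig_threshold=1.0, weak_threshold=1.5)


class TestExhaustiveEquivalence:
    def test_three_species_pool_matches_hand_enumeration(self, three_tip_tree):
        g = AssemblageGrid(cell_size=1.0, cells={
            (0, 0): frozenset({"A", "B"}), (1, 0): frozenset({"A", "C"})})
        cfg = NullModelConfig(max_iter=50, seed=0)
        m, audit = run_nri_analysis(g, three_tip_tree, cfg)
        m = m.set_index("cell_i")
        # exhaustive null MPDs {2, 4, 4}: mean 10/3, sample SD 2/sqrt(3)
        assert m.loc[0, "NRI"] == pytest.approx(+2 / np.sqrt(3), abs=1e-9)
        assert m.loc[1, "NRI"] == pytest.approx(-1 / np.sqrt(3), abs=1e-9)
        assert set(audit["stop_reason"]) == {"combinations_exhausted"}

    @pytest.mark.parametrize("seed", range(4))
    def test_random_small_pools_match_enumeration_oracle(self, seed):
        from conftest import random_grid, random_tree

        t = random_tree(n_tips=9, seed=700 + seed)
        labels = sorted(l.taxon.label for l in t.leaf_node_iter())
        g = random_grid(labels, n_cells=6, seed=seed, min_cell_size=2)
        g.cells = {c: frozenset(sorted(s)[:4]) for c, s in g.cells.items()}
        g.cells = {c: s for c, s in g.cells.items() if len(s) >= 2}
        cfg = NullModelConfig(max_iter=5000, seed=seed)
        m, _ = run_nri_analysis(g, t, cfg)
        pool = set().union(*g.cells.values())
        for row in m.itertuples(index=False):
            sp = g.cells[(row.cell_i, row.cell_j)]
            expected = exhaustive_null_z(t, pool, mpd_bruteforce(t, sp), len(sp))
            assert row.NRI == pytest.approx(expected, abs=1e-9)


class TestSharedNulls:
    def test_cells_with_equal_richness_share_null_moments(self):
        from conftest import random_tree

        t = random_tree(n_tips=12, seed=77)
        labels = sorted(l.taxon.label for l in t.leaf_node_iter())
        g = AssemblageGrid(cell_size=1.0, cells={
            (0, 0): frozenset(labels[:3]), (1, 0): frozenset(labels[4:7]),
            (2, 0): frozenset(labels[:12])})
        m, audit = run_nri_analysis(g, t, NullModelConfig(max_iter=200, seed=1))
        mpd_nulls = audit[audit.metric == "MPD"]
        assert len(mpd_nulls[mpd_nulls.S == 3]) == 1  # one shared class
        m = m.set_index("cell_i")
        assert m.loc[0, "NRI"] != m.loc[1, "NRI"]  # same null, different obs

    def test_regional_equals_continental_when_one_region_holds_all(self):
        from conftest import random_tree

        t = random_tree(n_tips=8, seed=5)
        labels = sorted(l.taxon.label for l in t.leaf_node_iter())
        cells = {(0, 0): frozenset(labels[:4]), (1, 0): frozenset(labels[3:])}
        g = AssemblageGrid(cell_size=1.0, cells=cells,
                           region_of={(0, 0): "only", (1, 0): "only"})
        mc, _ = run_nri_analysis(g, t, NullModelConfig(max_iter=300, seed=2))
        mr, _ = run_nri_analysis(
            g, t, NullModelConfig(pool_kind="regional", max_iter=300, seed=2))
        assert np.allclose(mc["NRI"].to_numpy(), mr["NRI"].to_numpy())

    def test_degenerate_full_pool_cell_flagged(self, three_tip_tree):
        g = AssemblageGrid(cell_size=1.0, cells={(0, 0): frozenset({"A", "B", "C"})})
        m, audit = run_nri_analysis(g, three_tip_tree, NullModelConfig(max_iter=10, seed=0))
        assert np.isnan(m.loc[0, "NRI"])
        assert m.loc[0, "class"] == "neutral_degenerate"
        assert audit["degenerate"].all()

    def test_regional_without_labels_rejected(self, three_tip_tree):
        g = AssemblageGrid(cell_size=1.0, cells={(0, 0): frozenset({"A", "B"})})
        with pytest.raises(ValueError, match="region"):
            run_nri_analysis(g, three_tip_tree,
                             NullModelConfig(pool_kind="regional", seed=0))

    def test_identical_seed_and_config_bitwise_identical(self):
        from conftest import random_grid, random_tree

        t = random_tree(n_tips=10, seed=6)
        labels = sorted(l.taxon.label for l in t.leaf_node_iter())
        g = random_grid(labels, n_cells=8, seed=6, min_cell_size=2)
        cfg = NullModelConfig(max_iter=99, seed=123)
        m1, a1 = run_nri_analysis(g, t, cfg)
        m2, a2 = run_nri_analysis(g, t, cfg)
        assert m1.to_csv() == m2.to_csv()
        assert a1.to_csv() == a2.to_csv()
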