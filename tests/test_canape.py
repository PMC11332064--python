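"""Null model, rank test and CANAPE classification rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import endemap as em
from endemap.canape import (
    NS,
    SIG_HIGH,
    SIG_LOW,
    UNDEFINED,
    NullModelConfig,
    SignificanceCodes,
    classify_canape,
    null_distributions,
    randomize_matrix,
    rank_test,
    relabel_masked,
)
from endemap.grid import Grid
from endemap.presence import PresenceMatrix
from endemap.synthetic import SyntheticConfig, plant_endemism


def small_matrix(values) -> PresenceMatrix:
    values = np.asarray(values, dtype=np.uint8)
    rows, cols = values.shape
    grid = Grid(0, 0, 1.0, 1 if rows == 1 else rows // 1, 1)
    # build a grid with exactly `rows` cells in one column
    grid = Grid(0, 0, 1.0, rows, 1)
    return PresenceMatrix(grid, [f"s{j}" for j in range(cols)], values)


class TestRandomizeMatrix:
    def test_all_zero_matrix_unchanged(self):
        m = small_matrix(np.zeros((4, 3)))
        r = randomize_matrix(m, n_swaps=100, seed=0)
        assert np.array_equal(r.values, m.values)

    def test_margins_preserved_exactly(self):
        rng = np.random.default_rng(1)
        m = small_matrix((rng.random((12, 8)) < 0.4).astype(int))
        for seed in range(5):
            r = randomize_matrix(m, n_swaps=500, seed=seed)
            assert np.array_equal(r.richness(), m.richness())
            assert np.array_equal(r.range_sizes(), m.range_sizes())

    def test_chain_visits_both_two_by_two_states(self):
        """2x2 identity incidence has exactly two fixed-margin states."""
        m = small_matrix(np.eye(2, dtype=int))
        seen = set()
        for seed in range(20):
            r = randomize_matrix(m, n_swaps=50, seed=seed)
            seen.add(tuple(r.values.reshape(-1).tolist()))
        assert seen == {(1, 0, 0, 1), (0, 1, 1, 0)}

    def test_seed_determinism_and_mixing(self):
        rng = np.random.default_rng(2)
        m = small_matrix((rng.random((20, 10)) < 0.3).astype(int))
        a = randomize_matrix(m, n_swaps=1000, seed=7)
        b = randomize_matrix(m, n_swaps=1000, seed=7)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, m.values)


class TestRankTest:
    def test_obs_above_all_999_nulls(self):
        code, p_high, _ = rank_test(1000.0, np.arange(999), alpha=0.05)
        assert p_high == pytest.approx(1 / 1000)
        assert code == SIG_HIGH

    def test_obs_equal_to_all_nulls_is_ns(self):
        code, p_high, p_low = rank_test(5.0, np.full(99, 5.0), alpha=0.05)
        assert p_high == p_low == 1.0
        assert code == NS

    def test_boundary_included(self):
        # 39 nulls, obs below all: p_low = 1/40 = 0.025 = alpha/2 -> sig
        code, _, p_low = rank_test(-1.0, np.arange(39), alpha=0.05)
        assert p_low == pytest.approx(0.025)
        assert code == SIG_LOW

    def test_undefined_observation(self):
        code, _, _ = rank_test(np.nan, np.arange(9), alpha=0.05)
        assert code == UNDEFINED

    def test_empty_nulls_rejected(self):
        with pytest.raises(ValueError):
            rank_test(1.0, [], alpha=0.05)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=60),
           st.floats(-60, 60))
    def test_p_values_are_valid_and_nested(self, nulls, obs):
        _, p_high, p_low = rank_test(obs, np.array(nulls), alpha=0.05)
        n = len(nulls)
        assert 1 / (n + 1) <= p_high <= 1.0
        assert 1 / (n + 1) <= p_low <= 1.0
        assert p_high + p_low >= 1.0  # ties counted on both sides
        # significance at 0.01 implies significance at 0.05
        c_strict, _, _ = rank_test(obs, np.array(nulls), alpha=0.01)
        c_loose, _, _ = rank_test(obs, np.array(nulls), alpha=0.05)
        if c_strict != NS:
            assert c_loose == c_strict


def _codes(pe, pe_alt, rpe_c, pe_s=NS, pe_alt_s=NS):
    return SignificanceCodes(
        at_alpha={"PE": np.array([pe], dtype=object),
                  "PE_alt": np.array([pe_alt], dtype=object),
                  "RPE": np.array([rpe_c], dtype=object)},
        at_alpha_super={"PE": np.array([pe_s], dtype=object),
                        "PE_alt": np.array([pe_alt_s], dtype=object),
                        "RPE": np.array([NS], dtype=object)},
    )


class TestClassifyCanape:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            (_codes(SIG_HIGH, NS, SIG_HIGH), "paleo"),
            (_codes(SIG_HIGH, SIG_HIGH, SIG_LOW), "neo"),
            (_codes(SIG_LOW, NS, SIG_LOW), "neo"),
            (_codes(SIG_HIGH, SIG_HIGH, NS), "mixed"),
            (_codes(SIG_HIGH, SIG_HIGH, NS, SIG_HIGH, SIG_HIGH), "super"),
            (_codes(NS, NS, NS), "non_significant"),
            (_codes(NS, SIG_HIGH, SIG_HIGH), "non_significant"),  # gate on PE
            (_codes(SIG_HIGH, NS, NS), "non_significant"),
            (_codes(UNDEFINED, UNDEFINED, UNDEFINED), "non_significant"),
        ],
    )
    def test_classification_table(self, codes, expected):
        assert classify_canape(codes)[0] == expected

    def test_strict_gate_admits_pe_alt_high(self):
        codes = _codes(NS, SIG_HIGH, SIG_LOW)
        assert classify_canape(codes)[0] == "non_significant"
        assert classify_canape(codes, strict_canape=True)[0] == "neo"


class TestRelabelMasked:
    def test_empty_cell_masked(self, toy_grid):
        m = PresenceMatrix.from_cell_sets(toy_grid, {"a": [0], "b": [0, 1]})
        classes = np.array(["neo", "paleo", "neo", "non_significant"],
                           dtype=object)
        out = relabel_masked(classes, m)
        assert out.tolist() == ["neo", "paleo", "masked", "masked"]

    def test_widespread_only_cells_masked(self, toy_grid):
        m = PresenceMatrix.from_cell_sets(
            toy_grid, {"wide": [0, 1, 2, 3], "other": [0]})
        classes = np.array(["paleo", "paleo", "paleo", "mixed"], dtype=object)
        out = relabel_masked(classes, m, widespread_only_species=["wide"])
        # cell 0 keeps both species -> untouched; 1-3 are widespread-only
        assert out.tolist() == ["paleo", "masked", "masked", "masked"]


class TestNullDistributions:
    def test_single_state_matrix_reproduces_observed(self, toy_grid, toy_tree):
        # all species everywhere: margins admit exactly one matrix
        m = PresenceMatrix.from_cell_sets(
            toy_grid, {s: list(range(4)) for s in ("A", "B", "C")})
        cfg = NullModelConfig(n_rand=1, seed=0)
        nulls = null_distributions(m, toy_tree, cfg)
        from endemap.metrics import build_branch_table
        pe_obs = em.phylo_endemism(m, build_branch_table(toy_tree, m.species))
        assert nulls["PE"][0] == pytest.approx(pe_obs)

    def test_determinism_and_seed_sensitivity(self):
        land = plant_endemism(SyntheticConfig(grid_rows=6, grid_cols=6,
                                              n_background_species=8, seed=0))
        c1 = NullModelConfig(n_rand=9, seed=5)
        a = null_distributions(land.presence, land.tree, c1)
        b = null_distributions(land.presence, land.tree, c1)
        assert np.array_equal(a["PE"], b["PE"])
        c = null_distributions(land.presence, land.tree,
                               NullModelConfig(n_rand=9, seed=6))
        assert not np.array_equal(a["PE"], c["PE"])

    def test_null_richness_equals_observed(self):
        """Row sums are fixed, so null SR = observed SR in every replicate;
        PE_alt depends on richness and ranges only, so empty cells stay
        empty and PE_alt > 0 wherever SR > 0."""
        land = plant_endemism(SyntheticConfig(grid_rows=6, grid_cols=6,
                                              n_background_species=8, seed=1))
        nulls = null_distributions(land.presence, land.tree,
                                   NullModelConfig(n_rand=19, seed=2))
        nonempty = land.presence.richness() > 0
        assert (nulls["PE_alt"][:, nonempty] > 0).all()
        assert np.isnan(nulls["RPE"][:, ~nonempty]).all()


def test_run_canape_output_structure(toy_grid, toy_tree, toy_presence):
    df = em.run_canape(toy_presence, toy_tree,
                       NullModelConfig(n_rand=19, seed=0))
    assert list(df["cell_id"]) == [0, 1, 2, 3]
    assert set(df["class"]).issubset(
        {"non_significant", "neo", "paleo", "mixed", "super", "masked"})
    assert (df["class_code"] >= 0).all()
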