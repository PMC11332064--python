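"""Greedy core-area prioritization: rule examples, oracle equivalence."""

import numpy as np
import pytest

import endemap as em
from endemap.prioritize import (
    Feature,
    build_features,
    core_area_rank,
    marginal_loss,
    performance_curves,
    top_fraction,
)
from endemap.synthetic import SyntheticConfig, plant_endemism

from conftest import naive_core_area_order


class TestMarginalLoss:
    def test_feature_entirely_in_one_cell(self):
        f = Feature("f", "taxon", 1.0, [1.0, 0.0, 0.0])
        assert marginal_loss(0, [f], remaining_totals=[1.0]) == 1.0

    def test_even_spread_quarter(self):
        f = Feature("f", "branch", 0.4, [1, 1, 1, 1])
        assert marginal_loss(2, [f], remaining_totals=[4.0]) == pytest.approx(0.1)

    def test_max_over_features_then_cost(self):
        f1 = Feature("a", "taxon", 0.3, [1.0, 0.0])
        f2 = Feature("b", "taxon", 0.5, [1.0, 0.0])
        cost = np.array([2.0, 1.0])
        val = marginal_loss(0, [f1, f2], remaining_totals=[1.0, 1.0], cost=cost)
        assert val == pytest.approx(0.25)


class TestCoreAreaRank:
    def test_hand_iterated_three_cell_example(self):
        # f1 = {c0} w=1; f2 spread over {c0, c1} w=0.5; c2 featureless
        f1 = Feature("f1", "taxon", 1.0, [1.0, 0.0, 0.0])
        f2 = Feature("f2", "taxon", 0.5, [0.5, 0.5, 0.0])
        ranking = core_area_rank([f1, f2], seed=0)
        assert ranking.removal_order.tolist() == [2, 1, 0]
        assert ranking.rank.tolist() == pytest.approx([1.0, 2 / 3, 1 / 3])

    def test_uniform_feature_last_cell_holds_everything(self):
        f = Feature("f", "taxon", 1.0, np.ones(12))
        for seed in (0, 1, 2):
            ranking = core_area_rank([f], seed=seed)
            last = ranking.removal_order[-1]
            assert ranking.rank[last] == 1.0

    def test_determinism_per_seed(self):
        rng = np.random.default_rng(3)
        feats = [Feature(f"f{j}", "taxon", 1.0, (rng.random(30) < 0.3) * 1.0)
                 for j in range(5)]
        a = core_area_rank(feats, seed=11)
        b = core_area_rank(feats, seed=11)
        assert np.array_equal(a.removal_order, b.removal_order)
        c = core_area_rank(feats, seed=12)
        assert not np.array_equal(a.removal_order, c.removal_order)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("warp", [1, 3])
    def test_matches_naive_full_recompute_oracle(self, seed, warp):
        rng = np.random.default_rng(100 + seed)
        n_cells = int(rng.integers(10, 50))
        n_feats = int(rng.integers(2, 10))
        amounts = (rng.random((n_cells, n_feats)) < 0.3).astype(float)
        amounts[:, amounts.sum(axis=0) == 0] = 1.0  # no empty features
        weights = rng.random(n_feats).round(3)
        cost = rng.integers(1, 3, n_cells).astype(float)
        feats = [Feature(f"f{j}", "taxon", weights[j], amounts[:, j])
                 for j in range(n_feats)]
        ranking = core_area_rank(feats, cost=cost, warp=warp, seed=seed)
        oracle = naive_core_area_order(amounts, weights, cost, seed, warp)
        assert ranking.removal_order.tolist() == oracle

    def test_single_cell_feature_survives_to_the_end(self):
        # one cell holds a full-range feature; others share a spread one
        solo = Feature("solo", "taxon", 1.0, [0, 0, 0, 0, 1.0])
        spread = Feature("spread", "taxon", 0.5, [1.0] * 5)
        for seed in range(3):
            ranking = core_area_rank([solo, spread], seed=seed)
            assert 4 in ranking.removal_order[-2:]


class TestTopFraction:
    def test_full_fraction_is_everything(self):
        f = Feature("f", "taxon", 1.0, np.ones(10))
        ranking = core_area_rank([f], seed=0)
        assert top_fraction(ranking, 1.0).tolist() == list(range(10))

    def test_ceiling_cell_count(self):
        f = Feature("f", "taxon", 1.0, np.ones(100))
        ranking = core_area_rank([f], seed=0)
        assert top_fraction(ranking, 0.17).size == 17
        assert top_fraction(ranking, 0.005).size == 1  # ceil

    def test_nestedness(self):
        rng = np.random.default_rng(4)
        feats = [Feature(f"f{j}", "taxon", 1.0, (rng.random(40) < 0.4) * 1.0)
                 for j in range(4)]
        ranking = core_area_rank(feats, seed=0)
        top17 = set(top_fraction(ranking, 0.17).tolist())
        top30 = set(top_fraction(ranking, 0.30).tolist())
        assert top17 <= top30

    def test_invalid_fraction(self):
        f = Feature("f", "taxon", 1.0, np.ones(4))
        ranking = core_area_rank([f], seed=0)
        with pytest.raises(ValueError):
            top_fraction(ranking, 0.0)


class TestBuildFeatures:
    def test_tx_features(self, toy_presence):
        feats = build_features("Tx", toy_presence)
        assert [f.id for f in feats] == ["A", "B", "C"]
        assert all(f.weight == 1.0 for f in feats)
        assert all(f.kind == "taxon" for f in feats)

    def test_br_weights_proportional_to_length(self, toy_presence, toy_tree):
        feats = build_features("Br", toy_presence, toy_tree)
        assert len(feats) == 4
        weights = sorted(f.weight for f in feats)
        assert weights == pytest.approx([0.2, 0.2, 0.2, 0.4])
        assert sum(f.weight for f in feats) == pytest.approx(1.0)
        # branch distribution is the union of descendant tip cells
        ab = next(f for f in feats if f.kind == "branch"
                  and f.distribution.sum() == 2 and "node" in f.id)
        assert ab.distribution.tolist() == [1, 1, 0, 0]

    def test_brce_adds_unit_weight_centers(self, toy_presence, toy_tree):
        classes = np.array(["neo", "non_significant", "paleo", "neo"],
                           dtype=object)
        feats = build_features("BrCE", toy_presence, toy_tree, classes)
        centers = [f for f in feats if f.kind == "center"]
        assert len(centers) == 1  # paleo and masked never become features
        assert centers[0].id == "center_neo"
        assert centers[0].weight == 1.0
        assert centers[0].distribution.tolist() == [1, 0, 0, 1]

    def test_brce_without_centers_warns_and_falls_back(self, toy_presence,
                                                       toy_tree):
        classes = np.array(["non_significant"] * 4, dtype=object)
        with pytest.warns(UserWarning):
            feats = build_features("BrCE", toy_presence, toy_tree, classes)
        assert all(f.kind == "branch" for f in feats)

    def test_unknown_scenario(self, toy_presence):
        with pytest.raises(ValueError):
            build_features("Xx", toy_presence)


def test_performance_curves_monotone_and_bounded(toy_presence, toy_tree):
    feats = build_features("Br", toy_presence, toy_tree)
    ranking = core_area_rank(feats, seed=0)
    curves = performance_curves(ranking, feats)
    assert curves.shape == (5, 4)
    assert (curves[0] == 1.0).all()
    assert (np.diff(curves, axis=0) <= 1e-12).all()  # non-increasing
    assert curves[-1] == pytest.approx(np.zeros(4))


def test_brce_covers_planted_neo_centers_better_than_br():
    """Targeting centers as features pulls neo cells into the top ranks."""
    land = plant_endemism(SyntheticConfig(seed=13))
    classes = np.full(land.grid.n_cells, "non_significant", dtype=object)
    classes[land.truth_labels == "neo"] = "neo"
    br = core_area_rank(build_features("Br", land.presence, land.tree),
                        seed=1)
    brce = core_area_rank(
        build_features("BrCE", land.presence, land.tree, classes), seed=1)
    neo_cells = set(np.flatnonzero(land.truth_labels == "neo").tolist())
    top_br = set(top_fraction(br, 0.05).tolist())
    top_brce = set(top_fraction(brce, 0.05).tolist())
    assert len(neo_cells & top_brce) >= len(neo_cells & top_br)
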