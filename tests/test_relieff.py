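"""ReliefF weighting against brute-force reference implementations."""

import numpy as np
import pytest

from oracles import naive_neighbors, naive_relieff
from trialcease.relieff import (
    RelieffConfig,
    diff,
    nearest_hits_misses,
    rank_and_select,
    relieff_weights,
)


class TestDiff:
    def test_nominal(self):
        assert diff(1.0, 1.0, "nominal") == 0.0
        assert diff(1.0, 0.0, "nominal") == 1.0

    def test_continuous_range_scaled(self):
        assert diff(2.0, 5.0, "continuous", (0.0, 10.0)) == pytest.approx(0.3)

    def test_constant_continuous_is_zero(self):
        assert diff(4.0, 4.0, "continuous", (4.0, 4.0)) == 0.0


class TestNearestHitsMisses:
    def test_two_per_class_forces_the_only_hit(self):
        X = np.array([[0.0], [0.1], [1.0], [0.9]])
        y = np.array([0, 0, 1, 1])
        hits, misses = nearest_hits_misses(0, X, y, k=1)
        assert list(hits) == [1]
        assert list(misses[1]) == [3]

    def test_identical_instances_tie_break_by_index(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        hits, misses = nearest_hits_misses(2, X, y, k=2)
        assert list(hits) == [0, 1]
        assert list(misses[1]) == [3, 4]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        X = rng.random((6, 2))
        y = np.array([0, 1, 0, 1, 0, 1])
        for i in range(6):
            hits, misses = nearest_hits_misses(i, X, y, k=2)
            exp_hits, exp_misses = naive_neighbors(X, y, i, k=2)
            assert list(hits) == exp_hits
            assert {c: list(v) for c, v in misses.items()} == exp_misses


class TestRelieffWeights:
    def test_constant_feature_scores_exactly_zero(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.random(20), np.full(20, 3.0)])
        y = np.array([0, 1] * 10)
        fw = relieff_weights(X, y, RelieffConfig(k_neighbors=3))
        assert fw.weights[1] == 0.0

    def test_four_instance_hand_example(self):
        """Perfectly separating nominal feature + constant feature, k=1.

        Every visited instance contributes -0/2 for its hit and +1/2 for its
        miss (equal priors make the miss factor 1), so the separating
        feature's weight is exactly 2.0 and the constant's exactly 0.
        """
        X = np.array([[0.0, 5.0], [0.0, 5.0], [1.0, 5.0], [1.0, 5.0]])
        y = np.array([0, 0, 1, 1])
        fw = relieff_weights(X, y, RelieffConfig(k_neighbors=1))
        np.testing.assert_allclose(fw.weights, [2.0, 0.0], atol=1e-15)
        np.testing.assert_allclose(
            fw.weights, naive_relieff(X, y, k=1), atol=1e-15
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_naive_reference_on_random_data(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(8, 30))
        m = int(rng.integers(1, 7))
        X = np.column_stack(
            [
                rng.integers(0, 2, n).astype(float)
                if rng.random() < 0.5
                else rng.random(n)
                for _ in range(m)
            ]
        )
        y = rng.integers(0, 2, n)
        while min((y == 0).sum(), (y == 1).sum()) < 3:
            y = rng.integers(0, 2, n)
        fw = relieff_weights(X, y, RelieffConfig(k_neighbors=2))
        np.testing.assert_allclose(fw.weights, naive_relieff(X, y, k=2), atol=1e-12)

    def test_normalizer_modes_rank_identically(self):
        rng = np.random.default_rng(9)
        X = rng.random((24, 5))
        y = rng.integers(0, 2, 24)
        paper = relieff_weights(X, y, RelieffConfig(k_neighbors=3, normalizer_mode="paper"))
        classic = relieff_weights(
            X, y, RelieffConfig(k_neighbors=3, normalizer_mode="classic")
        )
        assert np.argsort(-paper.weights).tolist() == np.argsort(-classic.weights).tolist()
        # uniform positive rescaling: m_features / n_iterations
        np.testing.assert_allclose(paper.weights * 5, classic.weights * 24, atol=1e-12)

    def test_duplicating_instances_preserves_separated_rankings(self):
        """Doubling every instance keeps informative features above noise.

        Duplication changes each instance's nearest hit (its own copy, at
        distance zero), so weights of near-tied features can reshuffle; the
        robust property is that a clearly class-separating feature stays
        ranked above noise and constant features.
        """
        rng = np.random.default_rng(5)
        noise = rng.random(30)
        separating = (rng.random(30) < 0.5).astype(float)
        constant = np.full(30, 2.0)
        X = np.column_stack([noise, separating, constant])
        y = separating.astype(int)
        for X_run, y_run in [(X, y), (np.vstack([X, X]), np.concatenate([y, y]))]:
            fw = relieff_weights(X_run, y_run, RelieffConfig(k_neighbors=2))
            assert fw.weights[1] > fw.weights[0]
            assert fw.weights[1] > fw.weights[2]
            assert fw.weights[2] == 0.0

    def test_adding_constant_feature_keeps_relative_order(self):
        rng = np.random.default_rng(6)
        X = rng.random((20, 4))
        y = rng.integers(0, 2, 20)
        base = relieff_weights(X, y, RelieffConfig(k_neighbors=2))
        augmented = relieff_weights(
            np.column_stack([X, np.ones(20)]), y, RelieffConfig(k_neighbors=2)
        )
        base_order = np.argsort(-base.weights, kind="stable").tolist()
        aug_order = [j for j in np.argsort(-augmented.weights, kind="stable") if j < 4]
        assert base_order == aug_order

    def test_small_class_is_named_in_error(self):
        X = np.random.default_rng(0).random((6, 2))
        y = np.array([0, 0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="1"):
            relieff_weights(X, y, RelieffConfig(k_neighbors=2))

    def test_sampled_policy_is_seeded(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 3))
        y = rng.integers(0, 2, 30)
        cfg = RelieffConfig(k_neighbors=2, iteration_policy="sampled", n_iterations=10, seed=3)
        a = relieff_weights(X, y, cfg)
        b = relieff_weights(X, y, cfg)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestRankAndSelect:
    def _fw(self, names, weights):
        from trialcease.relieff import FeatureWeights

        return FeatureWeights(
            names=names, weights=np.array(weights), config=RelieffConfig(), n_iterations=1
        )

    def test_tie_break_is_lexicographic(self):
        ranked = rank_and_select(self._fw(["a", "b", "c"], [0.2, 0.5, 0.2]), sizes=("all",))
        assert ranked.names == ["b", "a", "c"]

    def test_all_subset_is_identity(self):
        ranked = rank_and_select(self._fw(["a", "b"], [0.1, 0.2]), sizes=("all",))
        assert ranked.subsets["all"] == ["b", "a"]

    def test_oversized_request_clamps_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            ranked = rank_and_select(self._fw(["a", "b"], [0.1, 0.2]), sizes=(5,))
        assert ranked.subsets[5] == ["b", "a"]
        assert "clamped" in caplog.text
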