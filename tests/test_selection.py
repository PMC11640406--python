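"""Iterative NCA selection: weighting, prefix losses, greedy choice."""

import numpy as np
import pytest

from cardioish import (
    CVConfig,
    NCAConfig,
    choose,
    evaluate_prefixes,
    extract_features,
    generate_beatset,
    inca,
    minmax_normalize,
    nca_weights,
    nested_evaluate,
)
from cardioish.synthetic import example_profiles


@pytest.fixture
def toy_labels():
    return np.repeat([1, 2], 20)


@pytest.fixture
def toy_informative(toy_labels, rng):
    """Feature 1 tracks the class label up to tiny noise; feature 2 is noise."""
    return np.column_stack(
        [
            toy_labels + rng.normal(0, 0.01, len(toy_labels)),
            rng.normal(0, 1, len(toy_labels)),
        ]
    )


class TestMinmaxNormalize:
    def test_simple_column(self):
        Xn = minmax_normalize(np.array([[0.0], [0.5], [1.0]]))
        np.testing.assert_allclose(Xn[:, 0], [0.0, 0.5, 1.0], atol=1e-9)

    def test_constant_column_becomes_zero(self):
        Xn = minmax_normalize(np.full((5, 3), 0.3))
        np.testing.assert_array_equal(Xn, np.zeros((5, 3)))

    def test_range_of_nonconstant_columns(self, rng):
        X = rng.random((30, 6)) * 7 - 3
        Xn = minmax_normalize(X)
        np.testing.assert_allclose(Xn.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xn.max(axis=0), 1.0, atol=1e-6)
        assert np.all(Xn.max(axis=0) < 1.0)


class TestNCAWeights:
    def test_informative_feature_dominates(self, toy_informative, toy_labels):
        w, idx = nca_weights(minmax_normalize(toy_informative), toy_labels)
        assert w[0] ** 2 > w[1] ** 2
        assert idx[0] == 1

    def test_duplicated_feature_symmetry(self, toy_informative, toy_labels):
        X = np.column_stack(
            [toy_informative[:, 0], toy_informative[:, 0], toy_informative[:, 1]]
        )
        w, _ = nca_weights(minmax_normalize(X), toy_labels)
        assert w[0] ** 2 == pytest.approx(w[1] ** 2, rel=0.10)

    def test_heavy_regularization_collapses_to_index_order(
        self, toy_informative, toy_labels
    ):
        w, idx = nca_weights(
            minmax_normalize(toy_informative),
            toy_labels,
            NCAConfig(regularization=1e3),
        )
        assert np.max(np.abs(w)) < 1e-3
        np.testing.assert_array_equal(idx, [1, 2])

    def test_rejects_degenerate_labels(self, toy_informative):
        with pytest.raises(ValueError):
            nca_weights(minmax_normalize(toy_informative), np.ones(40, dtype=int))

    def test_deterministic(self, toy_informative, toy_labels):
        w1, idx1 = nca_weights(minmax_normalize(toy_informative), toy_labels)
        w2, idx2 = nca_weights(minmax_normalize(toy_informative), toy_labels)
        np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(idx1, idx2)


class TestEvaluatePrefixes:
    def test_separable_gives_zero_loss(self, toy_informative, toy_labels):
        Xn = minmax_normalize(toy_informative)
        loss, folds = evaluate_prefixes(
            Xn, toy_labels, np.array([1, 2]), 1, 2, CVConfig(folds=5, seed=0)
        )
        assert folds == 5
        assert loss[0] == 0.0  # the separating feature alone suffices
        assert np.all((loss >= 0) & (loss <= 1))

    def test_shuffled_labels_near_chance(self):
        """Random features, 2 balanced classes: mean 1-NN loss near 0.5."""
        rng = np.random.default_rng(77)
        X = rng.random((200, 10))
        y = np.repeat([1, 2], 100)
        ranking = np.arange(1, 11)
        loss, _ = evaluate_prefixes(X, y, ranking, 1, 10, CVConfig(folds=10, seed=0))
        assert abs(loss.mean() - 0.5) < 0.1

    def test_invalid_range_rejected(self, toy_informative, toy_labels):
        with pytest.raises(ValueError):
            evaluate_prefixes(toy_informative, toy_labels, np.array([1, 2]), 2, 1)


class TestChoose:
    @pytest.mark.parametrize(
        "loss,start,expected",
        [
            ((0.3, 0.1, 0.2), 1, 2),
            ((0.2, 0.1, 0.1), 1, 2),  # first minimum wins
            ((0.4, 0.4, 0.4), 1, 1),
            ((0.2, 0.1), 5, 6),
        ],
    )
    def test_greedy_first_minimum(self, loss, start, expected):
        assert choose(np.array(loss), start) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            choose(np.array([]))


class TestInca:
    @pytest.fixture
    def planted_beats(self, short_template):
        return generate_beatset(example_profiles(2), 15, short_template, rng_seed=3)

    def test_recovers_planted_signature(self, planted_beats, short_template):
        """Selected features must include a transition cell whose expected
        value differs between the two planted lead orderings."""
        from cardioish import beat_features, render_beat

        X, y = extract_features(planted_beats)
        result = inca(X, y, cv=CVConfig(folds=5, seed=0))
        profiles = example_profiles(2)
        f1 = beat_features(render_beat(short_template, profiles[0], 0))
        f2 = beat_features(render_beat(short_template, profiles[1], 0))
        planted_cells = set((np.nonzero(np.abs(f1 - f2) > 0.05)[0] + 1).tolist())
        assert planted_cells & set(result.sel_indexes.tolist())

    def test_contracts_and_determinism(self, planted_beats):
        X, y = extract_features(planted_beats)
        r1 = inca(X, y, cv=CVConfig(folds=5, seed=0))
        r2 = inca(X, y, cv=CVConfig(folds=5, seed=0))
        np.testing.assert_array_equal(r1.ranking, r2.ranking)
        np.testing.assert_array_equal(r1.loss, r2.loss)
        assert r1.chosen_size == r2.chosen_size
        # structural contracts
        assert sorted(r1.ranking) == list(range(1, 145))
        np.testing.assert_array_equal(r1.sel_indexes, r1.ranking[: r1.chosen_size])
        assert r1.loss[r1.chosen_size - r1.start] == r1.min_loss
        assert r1.min_loss <= r1.loss[-1]  # never worse than all features

    def test_stop_truncates_curve(self, planted_beats):
        X, y = extract_features(planted_beats)
        r = inca(X, y, stop=20, cv=CVConfig(folds=5, seed=0))
        assert len(r.loss) == 20
        assert r.chosen_size <= 20


class TestNestedEvaluate:
    def test_runs_and_scores_separable_data(self, short_template):
        beats = generate_beatset(example_profiles(2), 10, short_template, rng_seed=3)
        X, y = extract_features(beats)
        report = nested_evaluate(X, y, stop=20, cv=CVConfig(folds=4, seed=0))
        assert 0.0 <= report.accuracy <= 100.0
        assert report.accuracy == 100.0  # noise-free orderings stay separable
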