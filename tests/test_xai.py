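"""Symbolic layer: pair decoding, sentences, entropy, connectome graphs."""

import numpy as np
import pytest

from cardioish import (
    ALPHABET,
    build_connectome,
    build_sentence,
    feature_index_to_symbol_pair,
    flatten,
    sentence_transition_table,
    symbol_distribution,
    tokenize_sentence,
)
from cardioish.reference import (
    MENTAL_FREQUENCIES,
    MENTAL_SENTENCE,
    MI_FREQUENCIES,
    MI_SENTENCE,
)


class TestPairDecoding:
    @pytest.mark.parametrize(
        "u,expected",
        [(1, (1, 1)), (144, (12, 12)), (24, (2, 12)), (13, (2, 1)), (12, (1, 12))],
    )
    def test_worked_examples(self, u, expected):
        assert feature_index_to_symbol_pair(u) == expected

    def test_exhaustive_inverse_of_flatten(self):
        """Decoding u recovers exactly the (row, column) cell that the
        row-major flattening placed at position u, for all 144 indexes."""
        marker = np.arange(144, dtype=float).reshape(12, 12)
        fv = flatten(marker)
        for u in range(1, 145):
            x1, x2 = feature_index_to_symbol_pair(u)
            assert fv[u - 1] == marker[x1 - 1, x2 - 1]

    @pytest.mark.parametrize("u", [0, 145, -3])
    def test_out_of_range_rejected(self, u):
        with pytest.raises(IndexError):
            feature_index_to_symbol_pair(u)


class TestBuildSentence:
    def test_single_diagonal_feature(self):
        sentence = build_sentence([1])
        assert sentence.text == "Ld1Ld1"
        assert len(sentence) == 2

    def test_pair_order_follows_selection(self):
        sentence = build_sentence([24, 1])
        assert sentence.text == "Ld2V6LLd1Ld1"
        assert sentence.symbol_indexes == [2, 12, 1, 1]

    def test_token_count_contract(self, rng):
        sel = rng.choice(np.arange(1, 145), size=17, replace=False)
        assert len(build_sentence(sel)) == 34

    def test_empty_selection_is_valid(self):
        assert len(build_sentence([])) == 0


class TestTokenize:
    def test_simple(self):
        assert tokenize_sentence("AVLV1SV2S") == ["AVL", "V1S", "V2S"]

    def test_round_trip(self, rng):
        sel = rng.choice(np.arange(1, 145), size=10, replace=False)
        sentence = build_sentence(sel)
        assert tokenize_sentence(sentence.text) == sentence.tokens

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            tokenize_sentence("Ld1Ld")

    def test_unknown_chunk_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            tokenize_sentence("Ld1XXXV2S")


class TestReferenceSentences:
    """The published MI / mental-disorder sentences and frequency rows."""

    def test_mi_sentence_has_194_tokens(self):
        assert len(tokenize_sentence(MI_SENTENCE)) == 194
        assert sum(MI_FREQUENCIES) == 194

    def test_mi_frequency_row_reproduced(self):
        dist = symbol_distribution(tokenize_sentence(MI_SENTENCE))
        np.testing.assert_array_equal(dist.counts, MI_FREQUENCIES)
        assert dist.counts[ALPHABET.index("Ld3")] == 13

    def test_mental_frequency_row_reproduced(self):
        tokens = tokenize_sentence(MENTAL_SENTENCE)
        assert len(tokens) == 188
        dist = symbol_distribution(tokens)
        np.testing.assert_array_equal(dist.counts, MENTAL_FREQUENCIES)


class TestSymbolDistribution:
    def test_published_frequency_entropies(self):
        """The two published frequency rows give 3.5752 and 3.5637 bits."""
        mi = symbol_distribution(tokenize_sentence(MI_SENTENCE))
        mental = symbol_distribution(tokenize_sentence(MENTAL_SENTENCE))
        assert round(mi.entropy_bits, 4) == 3.5752
        assert round(mental.entropy_bits, 4) == 3.5637

    def test_uniform_counts_reach_max_entropy(self):
        tokens = list(ALPHABET) * 3
        dist = symbol_distribution(tokens)
        assert round(dist.entropy_bits, 4) == 3.5850
        assert dist.entropy_bits == pytest.approx(np.log2(12))

    def test_single_symbol_zero_entropy(self):
        assert symbol_distribution(["AVR"] * 9).entropy_bits == 0.0

    def test_probabilities_sum_to_one(self):
        dist = symbol_distribution(tokenize_sentence(MI_SENTENCE))
        assert dist.probabilities.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            symbol_distribution([])


class TestSentenceTransitionTable:
    def test_two_tokens(self):
        mat = sentence_transition_table(["Ld1", "Ld1"])
        assert mat[0, 0] == 1 and mat.sum() == 1

    def test_worked_example(self):
        mat = sentence_transition_table(["Ld2", "V6L", "Ld1", "Ld1"])
        assert mat[1, 11] == 1 and mat[11, 0] == 1 and mat[0, 0] == 1
        assert mat.sum() == 3

    def test_conservation(self, rng):
        tokens = [ALPHABET[i] for i in rng.integers(0, 12, 50)]
        assert sentence_transition_table(tokens).sum() == 49

    def test_short_input_warns_empty(self):
        with pytest.warns(UserWarning):
            mat = sentence_transition_table(["AVR"])
        assert mat.sum() == 0


class TestBuildConnectome:
    def test_empty_sentence_graph(self):
        g = build_connectome([], mode="sentence-transitions")
        assert g.number_of_nodes() == 12
        assert g.number_of_edges() == 0

    def test_edge_count_sum_is_tokens_minus_one(self, rng):
        sel = rng.choice(np.arange(1, 145), size=12, replace=False)
        sentence = build_sentence(sel)
        g = build_connectome(sentence)
        total = sum(d["count"] for _, _, d in g.edges(data=True))
        assert total == len(sentence) - 1

    def test_feature_pairs_mode_unit_counts(self):
        g = build_connectome([1, 24, 100], mode="feature-pairs")
        assert all(d["count"] == 1 for _, _, d in g.edges(data=True))
        assert g.number_of_edges() == 3

    def test_class_aggregate_mode(self, clean_beats):
        g = build_connectome(
            [1, 24], mode="class-aggregate", beats=clean_beats, class_label=1
        )
        assert g.number_of_nodes() == 12
        for _, _, d in g.edges(data=True):
            assert d["count"] >= 1

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown connectome mode"):
            build_connectome([1], mode="banana")
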