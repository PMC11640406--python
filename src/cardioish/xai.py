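"""Cardioish symbolic layer: sentences, symbol entropy, connectome graphs.

Each of the 144 transition features names an ordered pair of leads
(from-lead = transition-matrix row, to-lead = column).  Decoding the selected
feature indexes through the fixed 12-symbol alphabet and concatenating the
pairs in selection order yields a "sentence" of 3-character lead symbols.
Symbol frequencies, their Shannon entropy (bits, max log2(12) ≈ 3.5850), and
a directed 12-node transition graph (the cardiac "connectome") summarize
which leads — and which lead-to-lead transitions — carry the discriminative
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import entropy as _shannon_entropy

from .features import N_FEATURES
from .synthetic import N_LEADS, BeatSet

#: The fixed Cardioish alphabet, one 3-character symbol per lead, in the
#: conventional lead order I, II, III, aVR, aVL, aVF, V1..V6.
ALPHABET: tuple[str, ...] = (
    "Ld1", "Ld2", "Ld3", "AVR", "AVL", "AVF",
    "V1S", "V2S", "V3A", "V4A", "V5L", "V6L",
)

CONNECTOME_MODES = ("sentence-transitions", "feature-pairs", "class-aggregate")


def feature_index_to_symbol_pair(u: int) -> tuple[int, int]:
    """Decode 1-based feature index u into 1-based (from-lead, to-lead).

    Exact inverse of the row-major flattening: x1 = ceil(u/12),
    x2 = ((u-1) mod 12) + 1.
    """
    if not 1 <= u <= N_FEATURES:
        raise IndexError(f"feature index must be in 1..{N_FEATURES}, got {u}")
    return (u - 1) // N_LEADS + 1, (u - 1) % N_LEADS + 1


@dataclass
class CardioishSentence:
    """Ordered symbol-pair decoding of a feature selection."""

    tokens: list[str]
    symbol_indexes: list[int]  # 1-based, parallel to tokens

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.symbol_indexes):
            raise ValueError("tokens and symbol indexes must align")
        if len(self.tokens) % 2 != 0:
            raise ValueError("sentence length must be even (one pair per feature)")

    @property
    def n_features(self) -> int:
        return len(self.tokens) // 2

    @property
    def text(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class SymbolDistribution:
    """Symbol counts, probabilities and Shannon entropy of a token sequence."""

    counts: np.ndarray  # length 12, alphabet order
    probabilities: np.ndarray
    entropy_bits: float
    max_entropy_bits: float = field(default=float(np.log2(N_LEADS)))

    def to_dict(self) -> dict:
        return {
            "counts": {s: int(c) for s, c in zip(ALPHABET, self.counts)},
            "probabilities": {s: float(p) for s, p in zip(ALPHABET, self.probabilities)},
            "entropy_bits": self.entropy_bits,
            "max_entropy_bits": self.max_entropy_bits,
        }


def build_sentence(sel_indexes, alphabet: tuple[str, ...] = ALPHABET) -> CardioishSentence:
    """Decode ordered selected feature indexes (1-based) into a sentence.

    Token order follows the selection ranking: feature h contributes tokens
    2h-1 and 2h.  An empty selection yields a valid zero-length sentence.
    """
    tokens: list[str] = []
    sind: list[int] = []
    for u in np.asarray(sel_indexes, dtype=int):
        x1, x2 = feature_index_to_symbol_pair(int(u))
        tokens.extend((alphabet[x1 - 1], alphabet[x2 - 1]))
        sind.extend((x1, x2))
    return CardioishSentence(tokens, sind)


def tokenize_sentence(text: str, alphabet: tuple[str, ...] = ALPHABET) -> list[str]:
    """Split a concatenated-symbol sentence into its 3-character tokens."""
    if len(text) % 3 != 0:
        raise ValueError(f"sentence length {len(text)} is not a multiple of 3")
    valid = set(alphabet)
    tokens = [text[i : i + 3] for i in range(0, len(text), 3)]
    for pos, tok in enumerate(tokens):
        if tok not in valid:
            raise ValueError(f"unknown symbol {tok!r} at token position {pos + 1}")
    return tokens


def symbol_distribution(tokens: list[str]) -> SymbolDistribution:
    """Counts over the 12 symbols and base-2 Shannon entropy."""
    if len(tokens) == 0:
        raise ValueError("entropy of an empty token list is undefined")
    index = {s: i for i, s in enumerate(ALPHABET)}
    counts = np.zeros(N_LEADS, dtype=np.int64)
    for tok in tokens:
        try:
            counts[index[tok]] += 1
        except KeyError:
            raise ValueError(f"unknown symbol {tok!r}") from None
    probs = counts / counts.sum()
    return SymbolDistribution(
        counts=counts,
        probabilities=probs,
        entropy_bits=float(_shannon_entropy(probs, base=2)),
    )


def sentence_transition_table(tokens: list[str]) -> np.ndarray:
    """12×12 counts over consecutive token pairs, spanning pair boundaries."""
    import warnings

    index = {s: i for i, s in enumerate(ALPHABET)}
    mat = np.zeros((N_LEADS, N_LEADS), dtype=np.int64)
    if len(tokens) < 2:
        warnings.warn("fewer than 2 tokens: empty transition table")
        return mat
    ids = np.array([index[t] for t in tokens])
    np.add.at(mat, (ids[:-1], ids[1:]), 1)
    return mat


def _empty_graph(mode: str) -> nx.DiGraph:
    g = nx.DiGraph(mode=mode)
    g.add_nodes_from(ALPHABET)
    return g


def connectome_from_table(table: np.ndarray, mode: str) -> nx.DiGraph:
    g = _empty_graph(mode)
    table = np.asarray(table)
    for a, b in zip(*np.nonzero(table)):
        g.add_edge(ALPHABET[a], ALPHABET[b], count=int(table[a, b]))
    return g


def build_connectome(
    source,
    mode: str = "sentence-transitions",
    beats: BeatSet | None = None,
    class_label: int | None = None,
) -> nx.DiGraph:
    """Directed weighted 12-node graph on the Cardioish symbols.

    Modes:
      * ``sentence-transitions`` (default): ``source`` is a sentence or token
        list; edges are the nonzero cells of its symbol transition table.
      * ``feature-pairs``: ``source`` is the selected feature indexes; one
        edge per feature (from-lead -> to-lead), count = multiplicity.
      * ``class-aggregate``: ``source`` is the selected feature indexes;
        edge weights are the summed raw transition counts over the beats of
        ``class_label`` within ``beats``, restricted to the selected cells.
    """
    if mode not in CONNECTOME_MODES:
        raise ValueError(f"unknown connectome mode {mode!r}; choose from {CONNECTOME_MODES}")
    if mode == "sentence-transitions":
        tokens = source.tokens if isinstance(source, CardioishSentence) else list(source)
        if len(tokens) == 0:
            return _empty_graph(mode)
        return connectome_from_table(sentence_transition_table(tokens), mode)
    if mode == "feature-pairs":
        g = _empty_graph(mode)
        for u in np.asarray(source, dtype=int):
            x1, x2 = feature_index_to_symbol_pair(int(u))
            a, b = ALPHABET[x1 - 1], ALPHABET[x2 - 1]
            if g.has_edge(a, b):
                g[a][b]["count"] += 1
            else:
                g.add_edge(a, b, count=1)
        return g
    # class-aggregate
    from .features import count_transitions
    from .transform import transform_beat

    if beats is None or class_label is None:
        raise ValueError("class-aggregate mode needs `beats` and `class_label`")
    mask = beats.labels == class_label
    if not mask.any():
        raise ValueError(f"class {class_label} has no beats")
    total = np.zeros((N_LEADS, N_LEADS), dtype=np.int64)
    for beat in beats.signals[mask]:
        total += count_transitions(transform_beat(beat))
    selected = np.zeros_like(total)
    for u in np.asarray(source, dtype=int):
        x1, x2 = feature_index_to_symbol_pair(int(u))
        selected[x1 - 1, x2 - 1] = total[x1 - 1, x2 - 1]
    return connectome_from_table(selected, "class-aggregate")


def plot_connectome(graph: nx.DiGraph, ax=None, title: str | None = None):
    """Minimal circular rendering of a connectome graph (convenience only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.circular_layout(sorted(graph.nodes()))
    nx.draw_networkx_nodes(graph, pos, ax=ax, node_color="tab:red", node_size=900)
    nx.draw_networkx_labels(graph, pos, ax=ax, font_size=8, font_color="white")
    nx.draw_networkx_edges(graph, pos, ax=ax, connectionstyle="arc3,rad=0.1")
    labels = {(a, b): d["count"] for a, b, d in graph.edges(data=True)}
    nx.draw_networkx_edge_labels(graph, pos, edge_labels=labels, ax=ax, font_size=7)
    if title:
        ax.set_title(title)
    ax.set_axis_off()
    return ax
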