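"""Readers and writers for beat sets, feature tables, selection reports,
sentences, and connectome graphs.

Beat sets travel either as a pair of delimited text files (a long-format
signal table ``beat_id, lead_index, sample_index, value`` plus a labels table
``beat_id, label``) or as a compact NumPy ``.npz`` container holding the
``signals`` array, ``labels`` and ``lead_names``.  All indexes in text files
are 1-based, matching the public data model.

Graphs are written as GraphML, DOT, or node-link JSON; node ids are the
Cardioish symbols and the edge attribute ``count`` holds the integer weight.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .selection import SelectionResult
from .synthetic import DEFAULT_LEAD_NAMES, N_LEADS, BeatSet
from .xai import ALPHABET, CardioishSentence, symbol_distribution

FORMAT_TAGS = ("delimited", "binary")


class FormatError(ValueError):
    """A file failed structural validation; the message names the offender."""


@dataclass(frozen=True)
class DatasetManifest:
    signals_path: str | Path
    labels_path: str | Path | None = None
    format: str = "delimited"
    lead_names: tuple[str, ...] = DEFAULT_LEAD_NAMES
    expected_length: int | None = None

    def __post_init__(self) -> None:
        if self.format not in FORMAT_TAGS:
            raise ValueError(f"format must be one of {FORMAT_TAGS}, got {self.format!r}")
        if len(self.lead_names) != N_LEADS:
            raise FormatError(
                f"manifest must declare exactly {N_LEADS} leads, got {len(self.lead_names)}"
            )
        if self.format == "delimited" and self.labels_path is None:
            raise ValueError("delimited datasets need a labels file")


# ---------------------------------------------------------------- beat sets


def write_beatset(
    beats: BeatSet, signals_path: str | Path, labels_path: str | Path | None = None
) -> None:
    """Write a beat set as long-format CSV (+ labels CSV) or as .npz.

    The container is chosen by the signals path suffix: ``.npz`` selects the
    binary container (labels travel inside it), anything else the delimited
    text pair.
    """
    signals_path = Path(signals_path)
    if signals_path.suffix == ".npz":
        np.savez_compressed(
            signals_path,
            signals=beats.signals,
            labels=beats.labels,
            lead_names=np.array(beats.lead_names),
            label_names=json.dumps({str(k): v for k, v in beats.label_names.items()}),
        )
        return
    if labels_path is None:
        raise ValueError("delimited output needs a labels path")
    n, _, L = beats.signals.shape
    beat_id = np.repeat(np.arange(1, n + 1), N_LEADS * L)
    lead_index = np.tile(np.repeat(np.arange(1, N_LEADS + 1), L), n)
    sample_index = np.tile(np.arange(1, L + 1), n * N_LEADS)
    pd.DataFrame(
        {
            "beat_id": beat_id,
            "lead_index": lead_index,
            "sample_index": sample_index,
            "value": beats.signals.ravel(),
        }
    ).to_csv(signals_path, index=False)
    labels = [
        beats.label_names.get(int(lab), int(lab)) for lab in beats.labels
    ]
    pd.DataFrame({"beat_id": np.arange(1, n + 1), "label": labels}).to_csv(
        labels_path, index=False
    )


def _read_delimited(manifest: DatasetManifest) -> BeatSet:
    sig = pd.read_csv(manifest.signals_path)
    lab = pd.read_csv(manifest.labels_path)
    required = {"beat_id", "lead_index", "sample_index", "value"}
    if not required.issubset(sig.columns):
        raise FormatError(f"signal table missing columns {required - set(sig.columns)}")
    beat_ids = np.sort(sig["beat_id"].unique())
    known = set(beat_ids.tolist())
    label_ids = set(lab["beat_id"].tolist())
    for bid in lab["beat_id"]:
        if bid not in known:
            raise FormatError(f"labels file references beat_id {bid} absent from signals")
    lengths = set()
    signals = []
    for bid in beat_ids:
        if bid not in label_ids:
            raise FormatError(f"beat_id {bid} has no label")
        block = sig[sig["beat_id"] == bid]
        leads = np.sort(block["lead_index"].unique())
        if not np.array_equal(leads, np.arange(1, N_LEADS + 1)):
            raise FormatError(f"beat_id {bid}: expected leads 1..{N_LEADS}, got {leads.tolist()}")
        pivot = block.pivot(index="lead_index", columns="sample_index", values="value")
        if pivot.isna().any().any():
            raise FormatError(f"beat_id {bid}: missing samples in signal table")
        lengths.add(pivot.shape[1])
        signals.append(pivot.sort_index().to_numpy())
    if len(lengths) != 1:
        raise FormatError(f"inconsistent beat lengths across beats: {sorted(lengths)}")
    L = lengths.pop()
    if manifest.expected_length is not None and L != manifest.expected_length:
        raise FormatError(f"expected beat length {manifest.expected_length}, found {L}")
    lab = lab.set_index("beat_id").loc[beat_ids]
    raw_labels = lab["label"].tolist()
    uniq = sorted(set(raw_labels), key=lambda v: str(v))
    mapping = {v: i + 1 for i, v in enumerate(uniq)}
    labels = np.array([mapping[v] for v in raw_labels])
    label_names = {i + 1: str(v) for i, v in enumerate(uniq)}
    return BeatSet(np.stack(signals), labels, manifest.lead_names, label_names)


def read_beatset(manifest: DatasetManifest) -> BeatSet:
    """Read a beat set per its manifest; labels become contiguous 1..K."""
    if manifest.format == "binary":
        with np.load(manifest.signals_path, allow_pickle=False) as data:
            label_names = {
                int(k): v for k, v in json.loads(str(data["label_names"])).items()
            }
            return BeatSet(
                data["signals"],
                data["labels"],
                tuple(data["lead_names"].tolist()),
                label_names,
            )
    return _read_delimited(manifest)


# ------------------------------------------------------------ feature tables


def write_features(X: np.ndarray, y: np.ndarray, path: str | Path) -> None:
    """Feature table CSV with header f001..f144 plus a label column."""
    X = np.asarray(X)
    cols = [f"f{i:03d}" for i in range(1, X.shape[1] + 1)]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = np.asarray(y)
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise FormatError("feature table missing 'label' column")
    y = df.pop("label").to_numpy()
    return df.to_numpy(dtype=float), y


# --------------------------------------------------------- selection reports


def write_selection_report(result: SelectionResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


def read_selection_report(path: str | Path) -> SelectionResult:
    return SelectionResult.from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------- sentences


def write_sentence(sentence: CardioishSentence, path: str | Path) -> None:
    """Plain-text concatenated symbols plus a JSON sidecar (.json appended)."""
    path = Path(path)
    path.write_text(sentence.text + "\n")
    sidecar = {
        "tokens": sentence.tokens,
        "symbol_indexes_1based": sentence.symbol_indexes,
        "n_features": sentence.n_features,
    }
    if sentence.tokens:
        sidecar.update(symbol_distribution(sentence.tokens).to_dict())
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_sentence(path: str | Path) -> CardioishSentence:
    from .xai import tokenize_sentence

    text = Path(path).read_text().strip()
    tokens = tokenize_sentence(text)
    index = {s: i + 1 for i, s in enumerate(ALPHABET)}
    return CardioishSentence(tokens, [index[t] for t in tokens])


# -------------------------------------------------------------------- graphs

GRAPH_FORMATS = ("graphml", "dot", "json")


def _write_dot(graph: nx.DiGraph, path: Path) -> None:
    # minimal DOT writer: pydot/pygraphviz are optional upstream and absent here
    lines = ["digraph cardioish {"]
    for node in graph.nodes():
        lines.append(f'  "{node}";')
    for a, b, data in graph.edges(data=True):
        lines.append(f'  "{a}" -> "{b}" [count={int(data["count"])}];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


_DOT_EDGE = re.compile(r'^\s*"([^"]+)"\s*->\s*"([^"]+)"\s*\[count=(\d+)\];\s*$')
_DOT_NODE = re.compile(r'^\s*"([^"]+)";\s*$')


def _read_dot(path: Path) -> nx.DiGraph:
    g = nx.DiGraph()
    for line in path.read_text().splitlines():
        m = _DOT_EDGE.match(line)
        if m:
            g.add_edge(m.group(1), m.group(2), count=int(m.group(3)))
            continue
        m = _DOT_NODE.match(line)
        if m:
            g.add_node(m.group(1))
    return g


def write_connectome(graph: nx.DiGraph, path: str | Path, format: str = "graphml") -> None:
    """Serialize a connectome graph as GraphML, DOT, or node-link JSON."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "dot":
        _write_dot(graph, path)
    elif format == "json":
        payload = nx.node_link_data(graph, edges="edges")
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unsupported graph format {format!r}; choose from {GRAPH_FORMATS}")


def read_connectome(path: str | Path, format: str = "graphml") -> nx.DiGraph:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        out = nx.DiGraph()
        out.add_nodes_from(g.nodes())
        for a, b, data in g.edges(data=True):
            out.add_edge(a, b, count=int(data["count"]))
        return out
    if format == "dot":
        return _read_dot(path)
    if format == "json":
        payload = json.loads(path.read_text())
        return nx.node_link_graph(payload, directed=True, edges="edges")
    raise ValueError(f"unsupported graph format {format!r}; choose from {GRAPH_FORMATS}")
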