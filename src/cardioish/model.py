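"""Model/Results interface over the full explainable pipeline.

`CardioishModel` holds the data (a labelled beat set, or a precomputed
feature matrix) and the configuration; `fit()` runs feature extraction,
iterative NCA selection and cross-validated 1-NN evaluation, and returns a
`CardioishResults` carrying the selection trace, the evaluation report, the
decoded symbol sentence with its entropy, and the connectome graph, plus a
`summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify, features, selection, xai
from .classify import CVConfig, EvalReport
from .selection import NCAConfig, SelectionResult
from .synthetic import BeatSet, BeatTemplate, ClassProfile, generate_beatset
from .xai import CardioishSentence, SymbolDistribution


def fan_out_seeds(master_seed: int, n: int = 3) -> list[int]:
    """Derive n independent sub-seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass
class CardioishResults:
    """Fitted-pipeline outcome: selection, evaluation, symbolic explanation."""

    selection: SelectionResult
    evaluation: EvalReport
    sentence: CardioishSentence
    distribution: SymbolDistribution
    connectome: "object"  # networkx.DiGraph
    n_beats: int
    n_classes: int
    config: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.evaluation.accuracy

    @property
    def geometric_mean(self) -> float:
        return self.evaluation.geometric_mean

    @property
    def entropy_bits(self) -> float:
        return self.distribution.entropy_bits

    def plot_connectome(self, ax=None, title: str | None = None):
        return xai.plot_connectome(self.connectome, ax=ax, title=title)

    def summary(self) -> str:
        sel = self.selection
        lines = [
            "Cardioish pipeline results",
            "=" * 58,
            f"{'Beats':<34}{self.n_beats:>24}",
            f"{'Classes':<34}{self.n_classes:>24}",
            f"{'Features extracted':<34}{features.N_FEATURES:>24}",
            f"{'Features selected':<34}{sel.chosen_size:>24}",
            f"{'Selection loss (min)':<34}{sel.min_loss:>24.4f}",
            f"{'CV folds':<34}{self.evaluation.folds_used:>24}",
            f"{'Accuracy (%)':<34}{self.accuracy:>24.2f}",
            f"{'Geometric mean (%)':<34}{self.geometric_mean:>24.2f}",
            f"{'Sentence length (tokens)':<34}{len(self.sentence):>24}",
            f"{'Symbol entropy (bits)':<34}{self.entropy_bits:>24.4f}",
            f"{'Max entropy (bits)':<34}{self.distribution.max_entropy_bits:>24.4f}",
            "-" * 58,
            "Sentence:",
            self.sentence.text or "(empty)",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # keep the console readable
        return (
            f"<CardioishResults: {self.n_beats} beats, {self.n_classes} classes, "
            f"{self.selection.chosen_size} features, acc={self.accuracy:.2f}%>"
        )


class CardioishModel:
    """The explainable feature-engineering pipeline bound to one dataset.

    Parameters
    ----------
    beats : BeatSet, optional
        Raw 12-lead beats; features are extracted at fit time.
    X, y : arrays, optional
        Alternatively, a precomputed n×144 feature matrix with labels 1..K.
    epsilon : float
        Denominator guard used in row and min-max normalization.
    start, stop : int
        Prefix-size range swept by the iterative selector.
    nca_config, cv_config
        Hyperparameters for the NCA fit and the fold scheme (defaults:
        10-fold stratified, 1-NN with L1 distance).
    connectome_mode : str
        How the explanation graph is built (see `xai.build_connectome`).
    """

    def __init__(
        self,
        beats: BeatSet | None = None,
        X: np.ndarray | None = None,
        y: np.ndarray | None = None,
        *,
        epsilon: float = features.DEFAULT_EPSILON,
        start: int = 1,
        stop: int = features.N_FEATURES,
        nca_config: NCAConfig | None = None,
        cv_config: CVConfig | None = None,
        connectome_mode: str = "sentence-transitions",
    ) -> None:
        if beats is None and (X is None or y is None):
            raise ValueError("provide either a BeatSet or a feature matrix with labels")
        self.beats = beats
        self._X = None if X is None else np.asarray(X, dtype=float)
        self._y = None if y is None else np.asarray(y, dtype=int)
        self.epsilon = epsilon
        self.start = start
        self.stop = stop
        self.nca_config = nca_config or NCAConfig()
        self.cv_config = cv_config or CVConfig()
        self.connectome_mode = connectome_mode

    # ------------------------------------------------------------- builders

    @classmethod
    def from_beatset(cls, beats: BeatSet, **kwargs) -> "CardioishModel":
        return cls(beats=beats, **kwargs)

    @classmethod
    def from_features(cls, X: np.ndarray, y: np.ndarray, **kwargs) -> "CardioishModel":
        return cls(X=X, y=y, **kwargs)

    @classmethod
    def from_dataframe(cls, df, label_column: str = "label", **kwargs) -> "CardioishModel":
        """Build from a feature DataFrame with one label column."""
        y = df[label_column].to_numpy()
        X = df.drop(columns=[label_column]).to_numpy(dtype=float)
        return cls(X=X, y=y, **kwargs)

    @classmethod
    def from_synthetic(
        cls,
        profiles: list[ClassProfile],
        n_per_class: int,
        template: BeatTemplate | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "CardioishModel":
        return cls(beats=generate_beatset(profiles, n_per_class, template, seed), **kwargs)

    # ------------------------------------------------------------------ fit

    def extract(self) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and labels (computed from beats when needed)."""
        if self._X is None:
            self._X, self._y = features.extract_features(self.beats, self.epsilon)
        return self._X, self._y

    def fit(self) -> CardioishResults:
        X, y = self.extract()
        sel = selection.inca(
            X,
            y,
            start=self.start,
            stop=min(self.stop, X.shape[1]),
            nca_config=self.nca_config,
            cv=self.cv_config,
            epsilon=self.epsilon,
        )
        report = classify.cross_validate(sel.selected_columns(selection.minmax_normalize(X, self.epsilon)), y, self.cv_config)
        sentence = xai.build_sentence(sel.sel_indexes)
        dist = xai.symbol_distribution(sentence.tokens) if sentence.tokens else None
        if dist is None:
            raise RuntimeError("empty selection: no sentence to analyse")
        if self.connectome_mode == "feature-pairs":
            graph = xai.build_connectome(sel.sel_indexes, mode="feature-pairs")
        else:
            graph = xai.build_connectome(sentence, mode="sentence-transitions")
        return CardioishResults(
            selection=sel,
            evaluation=report,
            sentence=sentence,
            distribution=dist,
            connectome=graph,
            n_beats=len(y),
            n_classes=len(np.unique(y)),
            config={
                "epsilon": self.epsilon,
                "start": self.start,
                "stop": self.stop,
                "folds": self.cv_config.folds,
                "cv_seed": self.cv_config.seed,
                "nca_regularization": self.nca_config.regularization,
                "connectome_mode": self.connectome_mode,
            },
        )
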