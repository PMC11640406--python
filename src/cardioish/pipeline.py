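"""End-to-end orchestration: config parsing, artifact bundles, case studies.

A single `PipelineConfig` (JSON or YAML) describes the data source (a dataset
manifest or a synthetic specification), the feature-extraction epsilon, the
selection range, the fold scheme and the explanation mode.  `run_full` writes
a self-contained artifact bundle — features CSV, selection report, evaluation
report with confusion matrix, sentence, symbol distribution, connectome
graphs, and a provenance manifest recording every seed and parameter — from
which any artifact can be regenerated.

Defaults mirror the reference parameter block: descending-amplitude sorting,
144 transition features with row normalization, selection prefixes 1..144
scored by a 1-NN (L1) loss under 10-fold CV, greedy minimum-loss choice, and
entropy plus transition-table connectome generation with 12 symbols.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import features, io, selection
from .classify import CVConfig
from .model import CardioishModel, CardioishResults, fan_out_seeds
from .selection import NCAConfig
from .synthetic import BeatSet, BeatTemplate, ClassProfile, generate_beatset


@dataclass
class SyntheticSpec:
    """Synthetic data source: class profiles, beats per class, template."""

    profiles: list[dict]
    n_per_class: int = 100
    template: dict = field(default_factory=dict)

    def build(self, seed: int) -> BeatSet:
        template = BeatTemplate(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in self.template.items()
        })
        profiles = [
            ClassProfile(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in p.items()
            })
            for p in self.profiles
        ]
        return generate_beatset(profiles, self.n_per_class, template, seed)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    synthetic: SyntheticSpec | None = None
    manifest: io.DatasetManifest | None = None
    epsilon: float = features.DEFAULT_EPSILON
    start: int = 1
    stop: int = features.N_FEATURES
    regularization: float | None = None
    folds: int = 10
    seed: int = 0
    connectome_mode: str = "sentence-transitions"
    cases: list[list[int]] = field(default_factory=list)
    nested: bool = False

    def __post_init__(self) -> None:
        if self.synthetic is None and self.manifest is None:
            raise ValueError("config needs a data source: synthetic spec or manifest")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and d["synthetic"] is not None:
            d["synthetic"] = SyntheticSpec(**d["synthetic"])
        if "manifest" in d and d["manifest"] is not None:
            m = dict(d["manifest"])
            if "lead_names" in m:
                m["lead_names"] = tuple(m["lead_names"])
            d["manifest"] = io.DatasetManifest(**m)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)


def load_beats(config: PipelineConfig, data_seed: int) -> BeatSet:
    if config.synthetic is not None:
        return config.synthetic.build(data_seed)
    return io.read_beatset(config.manifest)


def build_model(config: PipelineConfig, beats: BeatSet, cv_seed: int, nca_seed: int) -> CardioishModel:
    return CardioishModel(
        beats=beats,
        epsilon=config.epsilon,
        start=config.start,
        stop=config.stop,
        nca_config=NCAConfig(regularization=config.regularization, seed=nca_seed),
        cv_config=CVConfig(folds=config.folds, seed=cv_seed),
        connectome_mode=config.connectome_mode,
    )


def run_case(
    beats: BeatSet,
    class_subset: list[int] | tuple[int, ...],
    config: PipelineConfig,
    cv_seed: int = 0,
    nca_seed: int = 0,
) -> CardioishResults:
    """Rerun the whole pipeline on a restricted class subset (e.g. one
    disorder vs control) and return its self-contained results."""
    if len(class_subset) < 2:
        raise ValueError("a case needs at least two classes")
    subset = beats.subset(tuple(class_subset))
    return build_model(config, subset, cv_seed, nca_seed).fit()


def run_full(config: PipelineConfig, out_dir: str | Path) -> CardioishResults:
    """Execute all four phases and write the artifact bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_seed, cv_seed, nca_seed = fan_out_seeds(config.seed, 3)
    beats = load_beats(config, data_seed)
    model = build_model(config, beats, cv_seed, nca_seed)
    X, y = model.extract()
    io.write_features(X, y, out / "features.csv")
    results = model.fit()
    io.write_selection_report(results.selection, out / "selection.json")
    (out / "evaluation.json").write_text(json.dumps(results.evaluation.to_dict(), indent=2))
    pd.DataFrame(results.evaluation.confusion).to_csv(out / "confusion.csv", index=False)
    io.write_sentence(results.sentence, out / "sentence.txt")
    (out / "distribution.json").write_text(json.dumps(results.distribution.to_dict(), indent=2))
    for fmt, name in (("graphml", "connectome.graphml"), ("dot", "connectome.dot"), ("json", "connectome.json")):
        io.write_connectome(results.connectome, out / name, format=fmt)
    case_summaries = []
    for case in config.cases:
        case_res = run_case(beats, case, config, cv_seed, nca_seed)
        tag = "-".join(str(c) for c in case)
        io.write_sentence(case_res.sentence, out / f"case_{tag}_sentence.txt")
        io.write_connectome(case_res.connectome, out / f"case_{tag}_connectome.graphml")
        case_summaries.append(
            {
                "classes": list(case),
                "accuracy_percent": case_res.accuracy,
                "chosen_size": case_res.selection.chosen_size,
                "entropy_bits": case_res.entropy_bits,
            }
        )
    if config.nested:
        nested_report = selection.nested_evaluate(
            X, y, config.start, config.stop,
            NCAConfig(regularization=config.regularization, seed=nca_seed),
            CVConfig(folds=config.folds, seed=cv_seed),
            config.epsilon,
        )
        (out / "evaluation_nested.json").write_text(
            json.dumps(nested_report.to_dict(), indent=2)
        )
    manifest = {
        "package_version": _pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "master_seed": config.seed,
        "derived_seeds": {"data": data_seed, "cv": cv_seed, "nca": nca_seed},
        "epsilon": config.epsilon,
        "start": config.start,
        "stop": config.stop,
        "regularization": config.regularization,
        "folds": config.folds,
        "connectome_mode": config.connectome_mode,
        "cases": case_summaries,
        "n_beats": int(beats.n_beats),
        "n_classes": int(beats.n_classes),
        "beat_length": int(beats.length),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
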