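"""Run configuration: one YAML document drives the full pipeline.

The configuration round-trips losslessly through YAML and hashes to a
stable identifier, so a run directory can always be traced back to the
exact corpus seed, split seed and classifier grid that produced it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .experiments import SplitSpec
from .synth import ClassAppearance, ClassLabel, CorpusConfig

log = logging.getLogger("safvision")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run depends on."""

    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    rbf_neurons: int = 25
    rbf_spread: float = 1.0
    rbf_algorithm: str | None = None
    sweep_neurons: tuple[int, ...] = (3, 5, 9, 13, 17, 21, 25, 29)
    sweep_spreads: tuple[float, ...] = (0.05, 0.2, 0.5, 0.95, 2.0, 5.0, 20.0)
    sweep_algorithms: tuple[str, ...] = ("T3", "T4", "T8", "T9", "T12")
    fractions: tuple[float, ...] = (0.8, 0.7, 0.6, 0.5)
    run_spectral: bool = True
    run_reports: bool = True
    classifier_seed: int = 0
    log_level: str = "INFO"


def _plain(obj):
    """Recursively convert tuples/enums so yaml.safe_dump can emit them."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, ClassLabel):
        return obj.value
    return obj


def to_yaml(config: RunConfig) -> str:
    data = asdict(config)
    data["corpus"]["classes"] = [
        {"label": lbl.value, **asdict(app)}
        for lbl, app in config.corpus.classes]
    return yaml.safe_dump(_plain(data), sort_keys=True)


def from_yaml(text: str) -> RunConfig:
    data = yaml.safe_load(text)
    corpus = data.get("corpus", {})
    if "classes" in corpus:
        corpus["classes"] = tuple(
            (ClassLabel(c.pop("label")),
             ClassAppearance(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in c.items()}))
            for c in [dict(c) for c in corpus["classes"]])
    for key in ("image_size", "spectral_size"):
        if key in corpus:
            corpus[key] = tuple(corpus[key])
    data["corpus"] = CorpusConfig(**corpus)
    data["split"] = SplitSpec(**data.get("split", {}))
    for key in ("sweep_neurons", "sweep_spreads", "sweep_algorithms",
                "fractions"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    """Stable hex digest identifying the configuration (seeds included)."""
    return hashlib.sha256(to_yaml(config).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    return from_yaml(Path(path).read_text())


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(to_yaml(config))
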