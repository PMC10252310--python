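"""Full pipeline runner: corpus -> features -> models -> report tables."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import FAMILIES, RBFNetworkClassifier
from .config import RunConfig, config_hash, save_config
from .experiments import (FEATURE_GROUPS, compare_classifiers,
                          generalizability, per_class_accuracy_report,
                          sensitivity_analysis, sweep_rbf)
from .features import FEATURE_NAMES, SELECTED_14
from .lsd import lsd_compare
from .pipeline import (chemistry_table, extract_feature_table,
                       extract_spectral_table, feature_matrix)
from .synth import generate_corpus

log = logging.getLogger("safvision")


def _rbf(config: RunConfig) -> RBFNetworkClassifier:
    return RBFNetworkClassifier(
        n_hidden=config.rbf_neurons, spread=config.rbf_spread,
        training_algorithm=config.rbf_algorithm,
        random_state=config.classifier_seed)


def plot_sweep(sweep: pd.DataFrame, path: Path) -> None:
    """Accuracy-vs-parameter curves per swept factor (one panel each)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    factors = sweep["factor"].unique()
    fig, axes = plt.subplots(1, len(factors), figsize=(4.5 * len(factors), 3.5))
    axes = np.atleast_1d(axes)
    for ax, factor in zip(axes, factors):
        sub = sweep[sweep["factor"] == factor]
        x = np.arange(len(sub))
        for phase in ("train", "test", "total"):
            ax.plot(x, sub[phase], marker="o", label=phase)
        ax.set_xticks(x, [str(v) for v in sub["value"]], rotation=45)
        ax.set_xlabel(factor)
        ax.set_ylabel("accuracy (%)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the configured stages in dependency order.

    Writes the corpus, feature/chemistry tables, comparison and sweep
    reports (table3 ... table8 style CSVs plus sweep plots), the resolved
    configuration and a structured log into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    digest = config_hash(config)
    log.info("run start: config hash %s", digest)
    save_config(config, out / "run_config.yaml")
    (out / "config_hash.txt").write_text(digest + "\n")

    try:
        stage = "corpus"
        corpus = generate_corpus(config.corpus, out_dir=out / "corpus")
        log.info("corpus: %d items in %d classes", len(corpus.items),
                 len(config.corpus.classes))

        stage = "features"
        features = extract_feature_table(corpus)
        features.to_csv(out / "features.csv", index=False)
        X, y = feature_matrix(features, FEATURE_NAMES)

        stage = "chemistry"
        chem = chemistry_table(corpus)
        chem.to_csv(out / "strengths.csv", index=False)
        chem_letters = {
            marker: lsd_compare({c: g[marker].to_numpy()
                                 for c, g in chem.groupby("class")}).letters
            for marker in ("crocin", "picrocrocin", "safranal")}
        pd.DataFrame(chem_letters).to_csv(out / "chemistry_lsd_letters.csv")

        if config.run_spectral and config.corpus.include_spectral:
            stage = "spectral"
            spectral = extract_spectral_table(corpus)
            spectral.to_csv(out / "spectral_features.csv", index=False)

        if not config.run_reports:
            log.info("run complete (reports disabled)")
            return out

        stage = "comparison"
        specs = {name: cls(random_state=config.classifier_seed)
                 for name, cls in FAMILIES.items()}
        specs["RBF"] = _rbf(config)
        table3 = compare_classifiers(X, y, specs, config.split)
        table3.to_csv(out / "table3.csv")

        stage = "per-class"
        table4 = per_class_accuracy_report(_rbf(config), X, y, config.split)
        table4.to_csv(out / "table4.csv")

        stage = "sweeps"
        sweep = sweep_rbf(X, y, config.split,
                          neurons=list(config.sweep_neurons),
                          spreads=list(config.sweep_spreads),
                          algorithms=list(config.sweep_algorithms),
                          base=_rbf(config))
        sweep.to_csv(out / "rbf_sweep.csv", index=False)
        plot_sweep(sweep, out / "rbf_sweep.png")

        stage = "sensitivity"
        table6 = sensitivity_analysis(features, y, config.split,
                                      groups=FEATURE_GROUPS, base=_rbf(config))
        table6.to_csv(out / "table6.csv")

        stage = "selected-per-class"
        Xsel, _ = feature_matrix(features, SELECTED_14)
        table7 = per_class_accuracy_report(_rbf(config), Xsel, y, config.split)
        table7.to_csv(out / "table7.csv")

        stage = "generalizability"
        table8 = generalizability(Xsel, y, fractions=config.fractions,
                                  base=_rbf(config), seed=config.split.seed)
        table8.to_csv(out / "table8.csv")
    except Exception:
        log.exception("stage %r failed; partial artifacts remain in %s",
                      stage, out)
        (out / "FAILED_STAGE.txt").write_text(stage + "\n")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    log.info("run complete: %s", out)
    return out
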