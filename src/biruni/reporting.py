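"""Pipeline orchestration and tabular report emission.

Runs the full sequential procedure — synthetic table (or CSV load) ->
feature selection -> classifier training -> optional hyperparameter tuning
-> held-out evaluation — and writes every artifact (mask JSON, model
bundles, metric report JSON, per-model metric CSV) stamped with the seed and
a hash of the configuration that produced it.  `render_comparison` turns
per-method accuracy vectors into the order-statistics summary, the pairwise
Wilcoxon table and the one-way ANOVA table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ber_core import BERSettings
from .binary_fs import FeatureMask, FSFitnessConfig, _wrapper_cv_error, select_features
from .eval_stats import (
    ConfusionCounts,
    compute_metrics,
    one_way_anova,
    wilcoxon_signed_rank,
)
from .lstm_mlp import (
    SequenceEncoding,
    TrainConfig,
    predict,
    train_lstm,
    train_mlp,
)
from .synthdata import FeatureTable, SynthSpec, generate_features
from .tuner import TuneBudget, default_space, tune_lstm

logger = logging.getLogger("biruni")

FORMAT_VERSION = 1
METRIC_COLUMNS = ["model", "ACC", "TPR", "TNR", "PPV", "NPV", "F1", "seconds"]


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; serializes losslessly to JSON."""

    seed: int = 0
    out_dir: str = "biruni_out"
    table_csv: str | None = None          # load instead of simulating
    synth: SynthSpec = field(default_factory=SynthSpec)
    run_fs: bool = True
    fs_alpha: float = 0.99
    fs_population: int = 10
    fs_iterations: int = 20
    models: tuple[str, ...] = ("lstm", "mlp")
    epochs: int = 50
    hidden_size: int = 32
    step_dim: int = 1
    run_tune: bool = False
    tune_population: int = 5
    tune_iterations: int = 5
    tune_search_epochs: int = 10
    test_fraction: float = 0.25
    format_version: int = FORMAT_VERSION

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthSpec(**d["synth"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _split_table(table: FeatureTable, test_fraction: float,
                 seed: int) -> tuple[FeatureTable, FeatureTable]:
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in np.unique(table.labels):
        idx = np.flatnonzero(table.labels == cls)
        rng.shuffle(idx)
        test_idx.append(idx[: int(round(test_fraction * idx.size))])
    test_mask = np.zeros(table.n_samples, dtype=bool)
    test_mask[np.concatenate(test_idx)] = True

    def subset(keep: np.ndarray) -> FeatureTable:
        return FeatureTable(
            values=table.values[keep], labels=table.labels[keep],
            feature_ids=table.feature_ids, provenance=table.provenance,
            informative_indices=table.informative_indices,
        )

    return subset(~test_mask), subset(test_mask)


def _restrict(table: FeatureTable, mask: FeatureMask) -> FeatureTable:
    idx = mask.indices()
    return FeatureTable(
        values=table.values[:, idx],
        labels=table.labels,
        feature_ids=[table.feature_ids[i] for i in idx],
        provenance=table.provenance,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the report bundle as a dict.

    Artifacts written to ``config.out_dir``: config.json, mask.json,
    model_<name>.json, report.json and metrics.csv.  A failing stage aborts
    with that stage named; artifacts written before the failure remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash(),
             "format_version": config.format_version}
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))

    stage = "load"
    try:
        if config.table_csv is not None:
            table = FeatureTable.from_csv(config.table_csv)
        else:
            table = generate_features(
                dataclasses.replace(config.synth, seed=config.seed)
            )

        stage = "split"
        train_table, test_table = _split_table(
            table, config.test_fraction, config.seed
        )

        stage = "select-features"
        fs_config = FSFitnessConfig(alpha=config.fs_alpha, seed=config.seed)
        if config.run_fs:
            ber = BERSettings(
                population_size=config.fs_population,
                iterations=config.fs_iterations, seed=config.seed,
            )
            mask, fs_fit, fs_traj = select_features(train_table, ber, fs_config)
        else:
            mask = FeatureMask(selected=np.ones(table.n_features, dtype=bool))
            fs_fit, fs_traj = None, []
        mask.to_json(out / "mask.json", fitness=fs_fit, seed=config.seed)
        train_sel = _restrict(train_table, mask)
        test_sel = _restrict(test_table, mask)

        stage = "train"
        rows = []
        report_models = {}
        for name in config.models:
            t0 = time.perf_counter()
            cfg = TrainConfig(epochs=config.epochs, hidden_size=config.hidden_size,
                              seed=config.seed)
            if name == "lstm":
                step_dim = config.step_dim if train_sel.n_features % config.step_dim == 0 else 1
                enc = SequenceEncoding.for_dimension(train_sel.n_features, step_dim)
                model = train_lstm(train_sel, enc, cfg)
            elif name == "mlp":
                model = train_mlp(train_sel, cfg)
            else:
                raise ValueError(f"unknown model {name!r}")
            seconds = time.perf_counter() - t0
            model.to_json(out / f"model_{name}.json")

            preds = (predict(model, test_sel.values) > 0.5).astype(int)
            counts = ConfusionCounts.from_predictions(test_sel.labels, preds)
            metrics = compute_metrics(counts, n_for_ci=test_sel.n_samples)
            report_models[name] = {
                "metrics": metrics.to_dict(),
                "confusion": dataclasses.asdict(counts),
                "train_accuracy_final": model.train_accuracy[-1],
                "val_accuracy_final": (model.val_accuracy[-1]
                                       if model.val_accuracy else None),
            }
            rows.append({
                "model": name,
                "ACC": metrics.accuracy, "TPR": metrics.sensitivity,
                "TNR": metrics.specificity, "PPV": metrics.ppv,
                "NPV": metrics.npv, "F1": metrics.f1,
                "seconds": round(seconds, 3),
            })

        stage = "tune"
        tune_report = None
        if config.run_tune:
            ber = BERSettings(population_size=config.tune_population,
                              iterations=config.tune_iterations,
                              seed=config.seed)
            res = tune_lstm(
                train_sel, default_space(train_sel.n_features), ber,
                budget=TuneBudget(search_epochs=config.tune_search_epochs,
                                  final_epochs=config.epochs),
            )
            tune_report = {
                "best_config": res.best_config,
                "best_validation_error": res.best_validation_error,
                "final_accuracy": res.final_accuracy,
                "evaluations": res.evaluations,
            }

        stage = "report"
        report = {
            **stamp,
            "n_samples": table.n_samples,
            "n_features": table.n_features,
            "selected_size": mask.size_ratio,
            "fs_fitness": fs_fit,
            "fs_trajectory": fs_traj,
            "models": report_models,
            "tune": tune_report,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(rows, columns=METRIC_COLUMNS).to_csv(
            out / "metrics.csv", index=False
        )
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Cross-method comparison tables
# ---------------------------------------------------------------------------

def render_comparison(runs: dict[str, np.ndarray],
                      out_dir: str | Path | None = None) -> dict:
    """Summary, pairwise-Wilcoxon and ANOVA tables over per-method run vectors.

    The first method in ``runs`` is treated as the proposed one and paired
    against each of the others.  All methods must have the same run count.
    Returns the tables as a dict; optionally also writes CSV renderings.
    """
    from .tuner import SUMMARY_ROWS, summarize_accuracies

    if len(runs) < 2:
        raise ValueError("need at least two methods to compare")
    lengths = {name: len(v) for name, v in runs.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"unequal run counts cannot be paired: {lengths}")

    names = list(runs)
    vectors = {n: np.asarray(v, dtype=float) for n, v in runs.items()}
    summary = {n: summarize_accuracies(v) for n, v in vectors.items()}

    proposed = names[0]
    wilcoxon = {}
    for other in names[1:]:
        res = wilcoxon_signed_rank(vectors[proposed] - vectors[other])
        wilcoxon[f"{proposed} vs {other}"] = {
            "W": res.w, "W_plus": res.w_plus, "W_minus": res.w_minus,
            "p_two_tailed": res.p_two_tailed, "method": res.method,
            "significant_at_0.05": res.p_two_tailed < 0.05,
        }

    anova = one_way_anova([vectors[n] for n in names]).to_dict()
    tables = {"summary": summary, "wilcoxon": wilcoxon, "anova": anova}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary_df = pd.DataFrame(
            {n: [summary[n][row] for row in SUMMARY_ROWS] for n in names},
            index=list(SUMMARY_ROWS),
        )
        summary_df.to_csv(out / "comparison_summary.csv")
        pd.DataFrame(wilcoxon).T.to_csv(out / "comparison_wilcoxon.csv")
        pd.DataFrame([anova]).to_csv(out / "comparison_anova.csv", index=False)
        (out / "comparison.json").write_text(json.dumps(tables, indent=2))
    return tables
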