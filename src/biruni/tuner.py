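"""BER-driven hyperparameter optimization of the LSTM classifier.

The optimizer searches the unit hypercube; each coordinate is decoded onto a
named hyperparameter axis (linear or log scale, integer/real/choice type).
An evaluation trains an LSTM with the decoded configuration under a reduced
epoch budget and scores it by validation error; the winning configuration is
retrained at the full budget.  The same harness runs a uniform-random
configuration search as a null control, and `replicate_runs` produces the
order-statistics summary used for cross-method comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import ber_core
from .ber_core import BERSettings, ObjectiveSpec
from .lstm_mlp import SequenceEncoding, TrainConfig, TrainedModel, train_lstm
from .synthdata import FeatureTable

logger = logging.getLogger("biruni")


# ---------------------------------------------------------------------------
# Hyperparameter space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperDimension:
    """One named axis: a bounded range or an explicit choice list."""

    name: str
    lo: float = 0.0
    hi: float = 1.0
    scale: str = "linear"         # {"linear", "log"}
    kind: str = "real"            # {"real", "integer", "choice"}
    choices: tuple = ()

    def __post_init__(self) -> None:
        if self.kind == "choice":
            if not self.choices:
                raise ValueError(f"choice dimension {self.name} needs choices")
        else:
            if not self.lo < self.hi:
                raise ValueError(f"dimension {self.name}: lo must be < hi")
            if self.scale == "log" and self.lo <= 0:
                raise ValueError(f"dimension {self.name}: log scale needs lo > 0")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        if self.kind not in ("real", "integer", "choice"):
            raise ValueError("kind must be 'real', 'integer' or 'choice'")

    def decode(self, u: float) -> float | int:
        u = min(max(float(u), 0.0), 1.0)
        if self.kind == "choice":
            idx = int(round(u * (len(self.choices) - 1)))
            return self.choices[idx]
        if self.scale == "log":
            v = 10 ** (math.log10(self.lo) + u * (math.log10(self.hi) - math.log10(self.lo)))
        else:
            v = self.lo + u * (self.hi - self.lo)
        if self.kind == "integer":
            return int(min(max(round(v), self.lo), self.hi))
        return float(min(max(v, self.lo), self.hi))


@dataclass(frozen=True)
class HyperSpace:
    dimensions: tuple[HyperDimension, ...]

    @property
    def k(self) -> int:
        return len(self.dimensions)

    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]


def default_space(feature_dim: int) -> HyperSpace:
    """Default LSTM search space; step_dim ranges over power-of-2 divisors."""
    divisors = tuple(
        m for m in (1, 2, 4, 8, 16, 32, 64) if feature_dim % m == 0
    )
    return HyperSpace(dimensions=(
        HyperDimension("hidden_size", 8, 256, scale="log", kind="integer"),
        HyperDimension("learning_rate", 1e-4, 1e-1, scale="log", kind="real"),
        HyperDimension("batch_size", 16, 128, scale="log", kind="integer"),
        HyperDimension("step_dim", kind="choice", choices=divisors),
    ))


def decode_position(position: np.ndarray, space: HyperSpace) -> dict:
    """Map a [0,1]^k vector to a named hyperparameter configuration."""
    position = np.asarray(position, dtype=float)
    if position.shape != (space.k,):
        raise ValueError(
            f"position length {position.shape} does not match space size {space.k}"
        )
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite")
    return {d.name: d.decode(u) for d, u in zip(space.dimensions, position)}


# ---------------------------------------------------------------------------
# Tuning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuneBudget:
    """Epoch budgets: reduced during search, full for the retrained winner."""

    search_epochs: int = 10
    final_epochs: int = 50


@dataclass
class TuneResult:
    best_config: dict
    best_validation_error: float
    trajectory: list[float]
    final_model: TrainedModel | None
    final_accuracy: float | None
    evaluations: int


def _config_to_train(config: dict, seed: int, epochs: int) -> TrainConfig:
    return TrainConfig(
        epochs=epochs,
        learning_rate=float(config.get("learning_rate", 0.01)),
        batch_size=int(config.get("batch_size", 32)),
        hidden_size=int(config.get("hidden_size", 32)),
        seed=seed,
    )


class _TuneObjective:
    """Validation error of an LSTM trained with the decoded configuration.

    Each evaluation derives its training seed deterministically from the run
    seed and the evaluation index, so the whole search is reproducible.
    Failed trainings score +inf and the search continues.
    """

    def __init__(self, table: FeatureTable, space: HyperSpace,
                 budget: TuneBudget, seed: int):
        self.table = table
        self.space = space
        self.budget = budget
        self.seed = seed
        self.calls = 0

    def eval_config(self, config: dict, epochs: int) -> tuple[float, TrainedModel | None]:
        eval_seed = (self.seed * 1_000_003 + self.calls) % (2**31)
        self.calls += 1
        try:
            enc = SequenceEncoding.for_dimension(
                self.table.n_features, step_dim=int(config.get("step_dim", 1))
            )
            model = train_lstm(self.table, enc,
                               _config_to_train(config, eval_seed, epochs))
        except (ValueError, FloatingPointError) as exc:
            logger.warning("tuning evaluation failed (%s); scoring +inf", exc)
            return math.inf, None
        val_err = 1.0 - model.val_accuracy[-1]
        return val_err, model

    def __call__(self, position: np.ndarray) -> float:
        config = decode_position(position, self.space)
        err, _ = self.eval_config(config, self.budget.search_epochs)
        return err


def tune_lstm(table: FeatureTable, space: HyperSpace, ber: BERSettings,
              budget: TuneBudget | None = None,
              retrain_final: bool = True) -> TuneResult:
    """Search the hyperparameter space with BER; retrain the winner fully."""
    budget = budget or TuneBudget()
    objective = _TuneObjective(table, space, budget, ber.seed)
    spec = ObjectiveSpec(
        dimension=space.k,
        lower_bounds=np.zeros(space.k),
        upper_bounds=np.ones(space.k),
        evaluate=objective,
        name="lstm-tuning",
    )
    result = ber_core.run(spec, ber)
    best_config = decode_position(result.best_position, space)

    final_model = None
    final_accuracy = None
    if retrain_final:
        _, final_model = objective.eval_config(best_config, budget.final_epochs)
        if final_model is not None:
            final_accuracy = final_model.val_accuracy[-1]
    return TuneResult(
        best_config=best_config,
        best_validation_error=result.best_fitness,
        trajectory=list(result.trajectory),
        final_model=final_model,
        final_accuracy=final_accuracy,
        evaluations=result.evaluations,
    )


def random_search_tune(table: FeatureTable, space: HyperSpace, n_configs: int,
                       budget: TuneBudget | None = None,
                       seed: int = 0) -> tuple[float, list[float]]:
    """Uniform-random configuration search with the same fitness.

    Returns (best validation error, all per-configuration errors); the
    null control against which tuned results are judged.
    """
    budget = budget or TuneBudget()
    objective = _TuneObjective(table, space, budget, seed)
    rng = np.random.default_rng(seed)
    errors = [
        float(objective(rng.uniform(size=space.k))) for _ in range(n_configs)
    ]
    return min(errors), errors


# ---------------------------------------------------------------------------
# Replication batteries and order-statistics summaries
# ---------------------------------------------------------------------------

#: Fixed row order of the comparison summary (byte-stable for regressions).
SUMMARY_ROWS = (
    "Number of values", "Minimum", "25% Percentile", "Median",
    "75% Percentile", "Maximum", "Mean", "Std. Deviation",
)


def summarize_accuracies(values: np.ndarray) -> dict[str, float]:
    """Order-statistics summary; quartiles use linear rank interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return {
        "Number of values": int(v.size),
        "Minimum": float(v.min()),
        "25% Percentile": float(q25),
        "Median": float(q50),
        "75% Percentile": float(q75),
        "Maximum": float(v.max()),
        "Mean": float(v.mean()),
        "Std. Deviation": (
            0.0 if v.size == 1 or v.max() == v.min() else float(v.std(ddof=1))
        ),
    }


def replicate_runs(table: FeatureTable, space: HyperSpace, ber: BERSettings,
                   budget: TuneBudget | None = None, m_runs: int = 10,
                   retrain_final: bool = True) -> tuple[np.ndarray, dict]:
    """M independent seeded tuning runs; final accuracy vector + summary."""
    if m_runs < 2:
        raise ValueError("m_runs must be >= 2")
    accuracies = []
    for j in range(m_runs):
        run_settings = replace(ber, seed=ber.seed + j)
        res = tune_lstm(table, space, run_settings, budget=budget,
                        retrain_final=retrain_final)
        if retrain_final and res.final_accuracy is not None:
            accuracies.append(res.final_accuracy)
        else:
            accuracies.append(1.0 - res.best_validation_error)
    vec = np.asarray(accuracies, dtype=float)
    return vec, summarize_accuracies(vec)
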