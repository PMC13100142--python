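"""Binary wrapper feature selection with BER, plus a binary-PSO control.

The continuous optimizer searches a box [-4, 4]^D; a position is mapped to a
feature mask by a sigmoid transfer with a fixed 0.5 threshold (coordinate j
is selected iff position_j > 0).  Candidate masks are scored by the composite
wrapper fitness

    fitness = alpha * CV_error(classifier | selected features)
            + (1 - alpha) * |selected| / D

so that, at the default alpha = 0.99, classification error dominates and the
size term breaks ties in favour of smaller subsets.  The default wrapper is
5-nearest-neighbours under 5-fold stratified cross-validation; an LSTM
wrapper is selectable but far more expensive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from . import ber_core
from .ber_core import BERSettings, ObjectiveSpec, OptimizerResult
from .synthdata import FeatureTable

#: Continuous search bounds for mask dynamics; sigmoid spans ~[0.018, 0.982].
MASK_BOUND = 4.0


@dataclass(frozen=True)
class FeatureMask:
    """Boolean selection over the columns of a feature table; never empty."""

    selected: np.ndarray

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=bool)
        object.__setattr__(self, "selected", sel)
        if sel.ndim != 1:
            raise ValueError("selected must be a 1-d boolean vector")
        if not sel.any():
            raise ValueError("a feature mask must select at least one feature")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def size_ratio(self) -> float:
        return self.n_selected / self.selected.size

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)

    def to_json(self, path: str | Path, fitness: float | None = None,
                seed: int | None = None) -> None:
        payload = {
            "selected": [int(i) for i in self.indices()],
            "D": int(self.selected.size),
        }
        if fitness is not None:
            payload["fitness"] = float(fitness)
        if seed is not None:
            payload["seed"] = int(seed)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureMask":
        payload = json.loads(Path(path).read_text())
        sel = np.zeros(payload["D"], dtype=bool)
        sel[payload["selected"]] = True
        return cls(selected=sel)


@dataclass(frozen=True)
class FSFitnessConfig:
    """Weighting, wrapper classifier and validation scheme of the FS fitness."""

    alpha: float = 0.99
    wrapper: str = "knn"           # {"knn", "lstm"}
    knn_k: int = 5
    n_folds: int = 5
    holdout: float | None = None   # if set, single stratified holdout instead of CV
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.wrapper not in ("knn", "lstm"):
            raise ValueError("wrapper must be 'knn' or 'lstm'")


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def binarize(position: np.ndarray) -> FeatureMask:
    """Sigmoid transfer with fixed 0.5 threshold (selected iff position > 0).

    If no coordinate clears the threshold the single coordinate with maximal
    sigmoid value is forced on (lowest index on ties), so masks are never
    empty.
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite")
    selected = sigmoid(position) > 0.5
    if not selected.any():
        selected = selected.copy()
        selected[int(np.argmax(position))] = True
    return FeatureMask(selected=selected)


def _wrapper_cv_error(mask: FeatureMask, table: FeatureTable,
                      config: FSFitnessConfig) -> float:
    """Cross-validated misclassification rate on the selected columns."""
    x = table.values[:, mask.selected]
    y = table.labels
    if config.wrapper == "lstm":
        from .lstm_mlp import SequenceEncoding, TrainConfig, lstm_cv_error
        return lstm_cv_error(x, y, seed=config.seed, n_folds=config.n_folds)

    class_counts = np.bincount(y)
    if (class_counts[class_counts > 0] < config.n_folds).any():
        raise ValueError(
            "a training fold would contain a single class; "
            "provide more samples or fewer folds"
        )
    splitter = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    errors = []
    for train_idx, test_idx in splitter.split(x, y):
        clf = KNeighborsClassifier(n_neighbors=config.knn_k)
        clf.fit(x[train_idx], y[train_idx])
        errors.append(float(np.mean(clf.predict(x[test_idx]) != y[test_idx])))
    return float(np.mean(errors))


def fs_fitness(mask: FeatureMask, table: FeatureTable,
               config: FSFitnessConfig) -> float:
    """Composite selection fitness: alpha*error + (1-alpha)*size ratio."""
    error = _wrapper_cv_error(mask, table, config)
    return config.alpha * error + (1.0 - config.alpha) * mask.size_ratio


class _CachedFitness:
    """Memoizes fitness by mask bytes; the wrapper CV is deterministic."""

    def __init__(self, table: FeatureTable, config: FSFitnessConfig):
        self.table = table
        self.config = config
        self.cache: dict[bytes, float] = {}
        self.calls = 0

    def __call__(self, position: np.ndarray) -> float:
        mask = binarize(position)
        key = np.packbits(mask.selected).tobytes()
        if key not in self.cache:
            self.cache[key] = fs_fitness(mask, self.table, self.config)
        self.calls += 1
        return self.cache[key]


def select_features(
    table: FeatureTable, ber: BERSettings, config: FSFitnessConfig
) -> tuple[FeatureMask, float, list[float]]:
    """Run BER over mask space; return (best mask, its fitness, trajectory)."""
    d = table.n_features
    objective = _CachedFitness(table, config)
    spec = ObjectiveSpec(
        dimension=d,
        lower_bounds=np.full(d, -MASK_BOUND),
        upper_bounds=np.full(d, MASK_BOUND),
        evaluate=objective,
        name="feature-selection",
    )
    result = ber_core.run(spec, ber)
    mask = binarize(result.best_position)
    return mask, result.best_fitness, list(result.trajectory)


# ---------------------------------------------------------------------------
# Binary PSO control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSOSettings:
    """Global-best PSO over the same continuous mask space."""

    population_size: int = 15
    iterations: int = 50
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    v_max: float = 2.0
    seed: int = 0


def select_features_bpso(
    table: FeatureTable, pso: PSOSettings, config: FSFitnessConfig
) -> tuple[FeatureMask, float, list[float]]:
    """Binary PSO with the same transfer rule and fitness as bBER."""
    d = table.n_features
    objective = _CachedFitness(table, config)
    rng = np.random.default_rng(pso.seed)
    n = pso.population_size

    pos = rng.uniform(-MASK_BOUND, MASK_BOUND, size=(n, d))
    vel = rng.uniform(-pso.v_max, pso.v_max, size=(n, d))
    fit = np.array([objective(p) for p in pos])

    pbest_pos = pos.copy()
    pbest_fit = fit.copy()
    g = int(np.argmin(fit))
    gbest_pos = pos[g].copy()
    gbest_fit = float(fit[g])
    trajectory = [gbest_fit]

    for _ in range(pso.iterations):
        rc = rng.uniform(size=(n, d))
        rs = rng.uniform(size=(n, d))
        vel = (
            pso.inertia * vel
            + pso.cognitive * rc * (pbest_pos - pos)
            + pso.social * rs * (gbest_pos - pos)
        )
        vel = np.clip(vel, -pso.v_max, pso.v_max)
        pos = np.clip(pos + vel, -MASK_BOUND, MASK_BOUND)
        fit = np.array([objective(p) for p in pos])
        improved = fit < pbest_fit
        pbest_pos[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest_pos = pbest_pos[g].copy()
        trajectory.append(gbest_fit)

    return binarize(gbest_pos), gbest_fit, trajectory


# ---------------------------------------------------------------------------
# Multi-run summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FSRunSummary:
    """Battery summary over M independent selection runs."""

    average_error: float
    average_select_size: float
    best_fitness: float
    worst_fitness: float
    mean_fitness: float
    sd_fitness: float
    m_runs: int


def summarize_runs(
    per_run_best: list[tuple[FeatureMask, float, float]]
) -> FSRunSummary:
    """Aggregate (mask, fitness, error) triples from M runs.

    The standard deviation uses the M-1 denominator and is defined as 0 for
    a single run.
    """
    if not per_run_best:
        raise ValueError("need at least one run to summarize")
    masks = [m for m, _, _ in per_run_best]
    fits = np.array([f for _, f, _ in per_run_best], dtype=float)
    errs = np.array([e for _, _, e in per_run_best], dtype=float)
    m = len(per_run_best)
    return FSRunSummary(
        average_error=float(errs.mean()),
        average_select_size=float(np.mean([mk.size_ratio for mk in masks])),
        best_fitness=float(fits.min()),
        worst_fitness=float(fits.max()),
        mean_fitness=float(fits.mean()),
        sd_fitness=0.0 if m == 1 else float(fits.std(ddof=1)),
        m_runs=m,
    )
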