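"""Download-free inputs: benchmark objectives and synthetic feature tables.

The feature-table generator emulates the structure of deep-feature matrices
extracted from radiographs: two imbalanced classes (Normal vs Osteoarthritis),
a small informative subset of features whose class means differ by a known
separation ``delta``, redundant correlated copies of those features, and
Gaussian nuisance noise.  Because the class-conditional model is Gaussian,
the Bayes error of any feature subset is known in closed form, which the
test batteries exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ber_core import ObjectiveSpec


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """samples x features matrix with binary labels (0=Normal, 1=Osteoarthritis)."""

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    provenance: str = ""
    informative_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d matrix")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match number of samples")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains missing values")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length must match number of features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: sample_id, label, then one column per feature."""
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", [f"s{i}" for i in range(self.n_samples)])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["sample_id", "label"]:
            raise ValueError("CSV must start with columns sample_id,label")
        values = df.iloc[:, 2:].to_numpy(dtype=float)
        return cls(
            values=values,
            labels=df["label"].to_numpy(dtype=int),
            feature_ids=list(df.columns[2:]),
            provenance=str(path),
        )


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings for a two-class Gaussian deep-feature surrogate.

    Defaults echo the study's class balance (1589 Normal / 2246 OA) at 1/10
    scale and use a desk-scale dimension of 100 (the full 1024 is available
    by flag).  ``k`` informative features are separated by ``delta`` between
    the class means; each gets one redundant copy with correlation ``rho``.
    """

    n_class0: int = 159
    n_class1: int = 225
    d: int = 100
    k: int = 10
    delta: float = 3.0
    rho: float = 0.7
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.d:
            raise ValueError("k (informative features) cannot exceed d")
        if 2 * self.k > self.d:
            raise ValueError("need d >= 2k to hold informative + redundant copies")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def generate_features(spec: SynthSpec) -> FeatureTable:
    """Generate a seeded two-class table with known informative features.

    Informative features: class-0 mean -delta/2, class-1 mean +delta/2, sd
    ``sigma``.  Features ``k..2k-1`` are redundant copies:
    rho * informative + sqrt(1 - rho^2) * fresh noise.  The rest are pure
    nuisance noise.  Ground-truth informative indices are attached to the
    returned table.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_class0 + spec.n_class1
    labels = np.concatenate(
        [np.zeros(spec.n_class0, dtype=int), np.ones(spec.n_class1, dtype=int)]
    )
    x = rng.normal(0.0, spec.sigma, size=(n, spec.d))
    signs = np.where(labels == 1, 0.5, -0.5)
    x[:, : spec.k] += spec.delta * signs[:, None]
    if spec.k > 0:
        noise = rng.normal(0.0, spec.sigma, size=(n, spec.k))
        x[:, spec.k : 2 * spec.k] = (
            spec.rho * x[:, : spec.k] + np.sqrt(1.0 - spec.rho**2) * noise
        )
    return FeatureTable(
        values=x,
        labels=labels,
        feature_ids=[f"f{j}" for j in range(spec.d)],
        provenance=f"synthetic:{spec}",
        informative_indices=np.arange(spec.k),
    )


#: Canned generator settings shared across the test suite.
FIXTURES: dict[str, SynthSpec] = {
    # small, cleanly separable
    "tiny_easy": SynthSpec(n_class0=60, n_class1=60, d=20, k=5, delta=6.0, seed=11),
    # overlapping classes, weak signal
    "tiny_hard": SynthSpec(n_class0=60, n_class1=60, d=20, k=5, delta=1.0, seed=13),
    # 1/10-scale echo of the study's 1589:2246 class imbalance
    "imbalanced_koa_like": SynthSpec(
        n_class0=159, n_class1=225, d=100, k=10, delta=3.0, seed=17
    ),
}


def make_fixture(name: str) -> FeatureTable:
    """Return one of the canned synthetic tables by name."""
    try:
        spec = FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}"
        ) from None
    table = generate_features(spec)
    table.provenance = f"fixture:{name}"
    return table


# ---------------------------------------------------------------------------
# Benchmark objectives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkFunction:
    name: str
    dimension: int
    lower: float
    upper: float
    optimum_position: np.ndarray = field(repr=False)
    optimum_value: float = 0.0

    def to_objective(self) -> ObjectiveSpec:
        return ObjectiveSpec(
            dimension=self.dimension,
            lower_bounds=np.full(self.dimension, self.lower),
            upper_bounds=np.full(self.dimension, self.upper),
            evaluate=_BENCHMARK_EVALUATORS[self.name],
            name=self.name,
        )

    def evaluate(self, position: np.ndarray) -> float:
        return _BENCHMARK_EVALUATORS[self.name](np.asarray(position, dtype=float))


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _sum_squares(x: np.ndarray) -> float:
    # weighted sphere: sum_i (i+1) * x_i^2
    return float(np.sum((np.arange(1, x.size + 1)) * x * x))


def _schwefel_2_22(x: np.ndarray) -> float:
    a = np.abs(x)
    return float(np.sum(a) + np.prod(a))


_BENCHMARK_EVALUATORS = {
    "sphere": _sphere,
    "sum_squares": _sum_squares,
    "schwefel_2_22": _schwefel_2_22,
}

_BENCHMARK_BOUNDS = {
    "sphere": (-100.0, 100.0),
    "sum_squares": (-100.0, 100.0),
    "schwefel_2_22": (-10.0, 10.0),
}


def make_benchmark(name: str, d: int) -> BenchmarkFunction:
    """Unimodal benchmark objective: sphere, sum_squares or schwefel_2_22.

    All three have their optimum 0 at the origin.
    """
    if name not in _BENCHMARK_EVALUATORS:
        raise ValueError(
            f"unknown benchmark {name!r}; choose from {sorted(_BENCHMARK_EVALUATORS)}"
        )
    if d <= 0:
        raise ValueError("dimension must be positive")
    lo, hi = _BENCHMARK_BOUNDS[name]
    return BenchmarkFunction(
        name=name, dimension=d, lower=lo, upper=hi,
        optimum_position=np.zeros(d), optimum_value=0.0,
    )
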