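"""Continuous Al-Biruni Earth Radius (BER) optimizer.

A population-based metaheuristic that splits its agents into an exploration
group and an exploitation group.  The exploitation share grows linearly from
30% to 70% of the population over the run.  Exploration perturbs an agent
around its own position; exploitation either steps toward the incumbent best
solution (the *leader*) or probes a slowly widening shell around it.  Elitism
keeps the leader alive across iterations, and agents whose fitness stalls for
a few consecutive iterations are replaced by a mutation draw, which maintains
population diversity.

Minimization is the internal convention throughout: objectives that are
naturally "higher is better" must be negated or converted to an error by the
caller.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("biruni")

#: Role labels for population members.
EXPLORATION = "exploration"
EXPLOITATION = "exploitation"


# ---------------------------------------------------------------------------
# Specifications and state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObjectiveSpec:
    """A box-bounded minimization problem.

    ``evaluate`` maps a position vector of length ``dimension`` to a real
    fitness and must be deterministic for a fixed position.
    """

    dimension: int
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    evaluate: Callable[[np.ndarray], float]
    name: str = "objective"

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower_bounds, dtype=float)
        hi = np.asarray(self.upper_bounds, dtype=float)
        object.__setattr__(self, "lower_bounds", lo)
        object.__setattr__(self, "upper_bounds", hi)
        if self.dimension <= 0:
            raise ValueError("dimension must be a positive integer")
        if lo.shape != (self.dimension,) or hi.shape != (self.dimension,):
            raise ValueError("bounds must be vectors of length `dimension`")
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if np.any(lo > hi):
            raise ValueError("lower_bounds must be <= upper_bounds elementwise")

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower_bounds, self.upper_bounds)


@dataclass(frozen=True)
class BERSettings:
    """Run-control parameters of the optimizer.

    ``exploit_fraction_start``/``_end`` give the 30% -> 70% exploitation
    schedule; ``stagnation_window`` iterations without an improvement larger
    than ``stagnation_tolerance`` trigger mutation of that agent.  ``r_cap``
    bounds the magnitude of the trigonometric step factor, whose defining
    ratio cos(x)/(1 - cos(x)) diverges as x -> 0; ``x_min_degrees`` keeps the
    angle draw away from that singularity.
    """

    population_size: int = 15
    iterations: int = 50
    exploit_fraction_start: float = 0.30
    exploit_fraction_end: float = 0.70
    stagnation_window: int = 3
    stagnation_tolerance: float = 1e-12
    r_cap: float = 10.0
    x_min_degrees: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        for f in (self.exploit_fraction_start, self.exploit_fraction_end):
            if not 0.0 <= f <= 1.0:
                raise ValueError("exploitation fractions must lie in [0, 1]")
        if not 0.0 < self.x_min_degrees <= 180.0:
            raise ValueError("x_min_degrees must lie in (0, 180]")
        if self.r_cap <= 0:
            raise ValueError("r_cap must be positive")
        if self.stagnation_window < 1:
            raise ValueError("stagnation_window must be >= 1")


@dataclass
class Agent:
    """One candidate solution: position, fitness, group role, stall counter."""

    position: np.ndarray
    fitness: float
    role: str = EXPLORATION
    stagnation_count: int = 0


@dataclass
class OptimizerState:
    """Mutable optimizer state carried between iterations."""

    agents: list[Agent]
    leader: Agent
    iteration: int
    rng: np.random.Generator
    best_history: list[float] = field(default_factory=list)
    evaluations: int = 0
    mutations_fired: int = 0


@dataclass(frozen=True)
class OptimizerResult:
    best_position: np.ndarray
    best_fitness: float
    trajectory: list[float]
    evaluations: int

    def to_dict(self) -> dict:
        return {
            "best_position": [float(v) for v in self.best_position],
            "best_fitness": float(self.best_fitness),
            "trajectory": [float(v) for v in self.trajectory],
            "evaluations": int(self.evaluations),
        }


# ---------------------------------------------------------------------------
# Elementary update rules
# ---------------------------------------------------------------------------

def sample_r(h: float, x_degrees: float, r_cap: float = 10.0) -> float:
    """Trigonometric step factor r = h*cos(x)/(1 - cos(x)), x in degrees.

    The ratio is unbounded as x -> 0 (cos x -> 1), so the result is clamped
    to ``[-r_cap, +r_cap]``.
    """
    if not 0.0 < x_degrees <= 180.0:
        raise ValueError("x_degrees must lie in (0, 180]")
    c = math.cos(math.radians(x_degrees))
    r = h * c / (1.0 - c)
    return float(np.clip(r, -r_cap, r_cap))


def exploration_step(position: np.ndarray, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Perturb an agent around its own position.

    D = r1 * (S - 1) elementwise (the scalar 1 broadcast over coordinates),
    and the move is S + D * (2*r2 - 1); the caller clips to bounds.
    """
    position = np.asarray(position, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if not (position.shape == r1.shape == r2.shape):
        raise ValueError("position, r1 and r2 must have identical shapes")
    d = r1 * (position - 1.0)
    return position + d * (2.0 * r2 - 1.0)


def exploit_toward_leader(
    position: np.ndarray, leader: np.ndarray, r: float, r3: np.ndarray
) -> np.ndarray:
    """Step toward the leader: r^2 * (S + r3 * (L - S))."""
    position = np.asarray(position, dtype=float)
    leader = np.asarray(leader, dtype=float)
    r3 = np.asarray(r3, dtype=float)
    if not (position.shape == leader.shape == r3.shape):
        raise ValueError("position, leader and r3 must have identical shapes")
    d = r3 * (leader - position)
    return (r * r) * (position + d)


def exploit_around_leader(
    leader: np.ndarray, r: float, z: float, t: int, n_iterations: int
) -> np.ndarray:
    """Probe a shell around the leader: r * (S* + k), k = z + 2*t^2/N^2.

    The offset k grows quadratically with the iteration index, widening the
    probed shell toward the end of the run.
    """
    if n_iterations == 0:
        raise ValueError("n_iterations must be positive")
    leader = np.asarray(leader, dtype=float)
    k = z + 2.0 * (t * t) / (n_iterations * n_iterations)
    return r * (leader + k)


def mutate(k: float, z: float, h: float, x_degrees: float, r_cap: float = 10.0) -> float:
    """Mutation draw for one coordinate: k*z^2 - h*cos(x)/(1 - cos(x)).

    The trigonometric term uses the same degree convention and cap as
    :func:`sample_r`.  Note the old position does not appear: mutation
    replaces the coordinate outright.
    """
    return k * z * z - sample_r(h, x_degrees, r_cap=r_cap)


def update_group_sizes(t: int, settings: BERSettings) -> tuple[int, int]:
    """Linear exploitation-share schedule; returns (n_exploit, n_explore).

    The share interpolates from ``exploit_fraction_start`` at t=0 to
    ``exploit_fraction_end`` at t=N.  Rounding is half-down (exact .5 ties
    floor) and each group keeps at least one member when n >= 2.
    """
    n = settings.population_size
    N = settings.iterations
    frac_t = t / N if N > 0 else 0.0
    frac = settings.exploit_fraction_start + (
        settings.exploit_fraction_end - settings.exploit_fraction_start
    ) * frac_t
    raw = frac * n
    n_exploit = math.floor(raw) + (1 if raw - math.floor(raw) > 0.5 else 0)
    if n >= 2:
        n_exploit = min(max(n_exploit, 1), n - 1)
    else:
        n_exploit = min(max(n_exploit, 0), n)
    return n_exploit, n - n_exploit


# ---------------------------------------------------------------------------
# Population machinery
# ---------------------------------------------------------------------------

def _safe_eval(spec: ObjectiveSpec, position: np.ndarray) -> float:
    value = float(spec.evaluate(position))
    if not math.isfinite(value):
        warnings.warn(
            f"non-finite fitness from objective '{spec.name}'; treating as +inf",
            RuntimeWarning,
            stacklevel=3,
        )
        logger.warning("objective %s returned non-finite fitness", spec.name)
        return math.inf
    return value


def _assign_roles(agents: list[Agent], n_exploit: int) -> None:
    for i, agent in enumerate(agents):
        agent.role = EXPLOITATION if i < n_exploit else EXPLORATION


def initialize_population(spec: ObjectiveSpec, settings: BERSettings) -> OptimizerState:
    """Draw the initial population uniformly inside the bounds and rank it."""
    rng = np.random.default_rng(settings.seed)
    n = settings.population_size
    positions = rng.uniform(
        spec.lower_bounds, spec.upper_bounds, size=(n, spec.dimension)
    )
    agents = [
        Agent(position=positions[i].copy(), fitness=_safe_eval(spec, positions[i]))
        for i in range(n)
    ]
    n_exploit, _ = update_group_sizes(0, settings)
    _assign_roles(agents, n_exploit)
    best = min(agents, key=lambda a: a.fitness)
    leader = Agent(position=best.position.copy(), fitness=best.fitness, role=best.role)
    return OptimizerState(
        agents=agents,
        leader=leader,
        iteration=0,
        rng=rng,
        best_history=[leader.fitness],
        evaluations=n,
    )


def step(state: OptimizerState, spec: ObjectiveSpec, settings: BERSettings) -> OptimizerState:
    """One iteration of the BER dynamics, in place; returns ``state``.

    Order of operations: move every agent with its group's rule, clip to
    bounds, re-evaluate, update the leader (strict improvement only), mutate
    stalled agents, reinsert the leader over the current worst agent if it is
    no longer present, shuffle the agent order and refresh group sizes.
    """
    rng = state.rng
    t = state.iteration + 1
    N = max(settings.iterations, 1)
    d = spec.dimension

    for agent in state.agents:
        if agent.role == EXPLORATION:
            r1 = rng.uniform(0.0, 1.0, size=d)
            r2 = rng.uniform(0.0, 1.0, size=d)
            new_pos = exploration_step(agent.position, r1, r2)
        else:
            h = rng.uniform(0.0, 2.0)
            x = rng.uniform(settings.x_min_degrees, 180.0)
            r = sample_r(h, x, r_cap=settings.r_cap)
            if rng.uniform() < 0.5:
                r3 = rng.uniform(0.0, 1.0, size=d)
                new_pos = exploit_toward_leader(
                    agent.position, state.leader.position, r, r3
                )
            else:
                z = rng.uniform(0.0, 1.0)
                new_pos = exploit_around_leader(state.leader.position, r, z, t, N)
        new_pos = spec.clip(new_pos)
        new_fit = _safe_eval(spec, new_pos)
        state.evaluations += 1
        if new_fit < agent.fitness - settings.stagnation_tolerance:
            agent.stagnation_count = 0
        else:
            agent.stagnation_count += 1
        agent.position = new_pos
        agent.fitness = new_fit

    # Stagnation-triggered mutation: replace the whole position of any agent
    # that has not improved for `stagnation_window` consecutive iterations.
    for agent in state.agents:
        if agent.stagnation_count >= settings.stagnation_window:
            k = rng.uniform(0.0, 1.0) + 2.0 * (t * t) / (N * N)
            mutated = np.array(
                [
                    mutate(
                        k,
                        rng.uniform(0.0, 1.0),
                        rng.uniform(0.0, 2.0),
                        rng.uniform(settings.x_min_degrees, 180.0),
                        r_cap=settings.r_cap,
                    )
                    for _ in range(d)
                ]
            )
            agent.position = spec.clip(mutated)
            agent.fitness = _safe_eval(spec, agent.position)
            state.evaluations += 1
            state.mutations_fired += 1
            agent.stagnation_count = 0

    # Elitism: the leader only ever improves, and survives in the population.
    best = min(state.agents, key=lambda a: a.fitness)
    if best.fitness < state.leader.fitness:
        state.leader = Agent(
            position=best.position.copy(), fitness=best.fitness, role=best.role
        )
    if not any(
        a.fitness == state.leader.fitness and np.array_equal(a.position, state.leader.position)
        for a in state.agents
    ):
        worst_idx = max(range(len(state.agents)), key=lambda i: state.agents[i].fitness)
        state.agents[worst_idx] = Agent(
            position=state.leader.position.copy(),
            fitness=state.leader.fitness,
            role=state.agents[worst_idx].role,
        )

    # Random re-ranking keeps group membership churning between iterations.
    rng.shuffle(state.agents)
    n_exploit, n_explore = update_group_sizes(t, settings)
    _assign_roles(state.agents, n_exploit)

    state.iteration = t
    state.best_history.append(state.leader.fitness)
    logger.debug(
        "iter=%d best=%.6g n_exploit=%d n_explore=%d mutations=%d",
        t, state.leader.fitness, n_exploit, n_explore, state.mutations_fired,
    )
    return state


def run(spec: ObjectiveSpec, settings: BERSettings) -> OptimizerResult:
    """Full optimization: initialize, iterate ``settings.iterations`` times."""
    state = initialize_population(spec, settings)
    for _ in range(settings.iterations):
        step(state, spec, settings)
    return OptimizerResult(
        best_position=state.leader.position.copy(),
        best_fitness=state.leader.fitness,
        trajectory=list(state.best_history),
        evaluations=state.evaluations,
    )


def run_random_search(spec: ObjectiveSpec, n_evaluations: int, seed: int) -> OptimizerResult:
    """Uniform random search with the same evaluation budget: a null control."""
    rng = np.random.default_rng(seed)
    best_pos: np.ndarray | None = None
    best_fit = math.inf
    trajectory: list[float] = []
    for _ in range(n_evaluations):
        pos = rng.uniform(spec.lower_bounds, spec.upper_bounds, size=spec.dimension)
        fit = _safe_eval(spec, pos)
        if fit < best_fit:
            best_fit = fit
            best_pos = pos
        trajectory.append(best_fit)
    if best_pos is None:
        raise ValueError("n_evaluations must be >= 1")
    return OptimizerResult(
        best_position=best_pos, best_fitness=best_fit,
        trajectory=trajectory, evaluations=n_evaluations,
    )
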