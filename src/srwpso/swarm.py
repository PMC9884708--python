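"""Canonical PSO and the boosted SRWPSO variant.

SRWPSO augments particle swarm optimization with three independently
switchable strategies:

* **SOB** — Sobol low-discrepancy initialization of the population, giving a
  more uniform coverage of the search box than pseudo-random sampling.
* **RRS** — random replacement: each personal-best coordinate is replaced by
  the corresponding global-best coordinate when a linearly decaying
  probability parameter ``a = 1 - FEs/MaxFEs`` falls below a fresh standard
  Cauchy draw; the hybridized personal best is re-evaluated, injecting
  diversity early and exploiting the incumbent late.
* **AWS** — adaptive inertia weight ``omega = (1 - FEs/MaxFEs)**beta`` with
  ``beta = 1 - C1*S/MaxFEs``; the Cauchy draw ``C1`` and the adaptive scalar
  ``S`` (halved when the global best improves, incremented otherwise) let the
  weight jump off its linearly decaying trajectory.

The optimizers are evaluation-budgeted (``MaxFEs``), fully deterministic for
a fixed seed, and record a ``(FEs, best_score)`` trace after every
evaluation batch for convergence curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .objectives import ObjectiveSpec

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "OptimizeResult",
    "init_random_population",
    "init_sobol_population",
    "cauchy_sample",
    "decay_factor",
    "random_replacement",
    "adaptive_weight",
    "update_S",
    "velocity_update",
    "position_update",
    "update_bests",
    "run_pso",
    "run_srwpso",
    "ABLATION_VARIANTS",
]

# strategy-flag combinations defining the ablation family
# (Sobol init, random replacement, adaptive weight)
ABLATION_VARIANTS: dict[str, tuple[bool, bool, bool]] = {
    "SRWPSO": (True, True, True),
    "SRPSO": (True, True, False),
    "SWPSO": (True, False, True),
    "RWPSO": (False, True, True),
    "SOBPSO": (True, False, False),
    "RRPSO": (False, True, False),
    "AWPSO": (False, False, True),
    "PSO": (False, False, False),
}


@dataclass
class SwarmConfig:
    """Run-time constants of a swarm optimization run.

    Defaults follow the benchmark setup (population 30, budget 300,000
    evaluations, Vmax 6, c1 = c2 = 2, initial adaptive scalar S = 0.01,
    bounds [-100, 100]); feature-selection runs use population 20.
    """

    dim: int
    population_size: int = 30
    max_evaluations: int = 300_000
    v_max: float = 6.0
    c1: float = 2.0
    c2: float = 2.0
    s_init: float = 0.01
    use_sobol: bool = True
    use_rrs: bool = True
    use_aws: bool = True
    seed: int = 0
    lower_bound: float = -100.0
    upper_bound: float = 100.0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_evaluations < self.population_size:
            raise ValueError(
                "max_evaluations must be >= population_size "
                "(cannot complete the initial evaluation pass)"
            )
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be strictly below upper_bound")


@dataclass
class SwarmState:
    """Mutable state of a running swarm."""

    positions: np.ndarray
    velocities: np.ndarray
    personal_best: np.ndarray
    personal_best_score: np.ndarray
    global_best: np.ndarray
    global_best_score: float
    evaluations_used: int = 0
    adaptive_S: float = 0.01
    iteration: int = 0


@dataclass
class OptimizeResult:
    """Outcome of an optimization run.

    ``trace`` holds ``(evaluations_used, best_score)`` checkpoints recorded
    after every evaluation batch; best_score is monotone non-increasing.
    """

    best_position: np.ndarray
    best_score: float
    trace: list[tuple[int, float]] = field(default_factory=list)
    evaluations_used: int = 0


def init_random_population(config: SwarmConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform random positions in the search box (one particle per row)."""
    return rng.uniform(
        config.lower_bound,
        config.upper_bound,
        size=(config.population_size, config.dim),
    )


def init_sobol_population(config: SwarmConfig, rng: np.random.Generator) -> np.ndarray:
    """Sobol low-discrepancy positions, X_i = lb + S_i * (ub - lb).

    Owen-scrambled Sobol points seeded from ``rng`` are used: scrambling
    keeps the low-discrepancy guarantee while randomizing the point set per
    seed, so repeated runs explore different initializations (like the
    uniform initializer) and no deterministic sequence point — the plain
    sequence starts at the box corner and center — is planted in every
    population.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sampler = qmc.Sobol(d=config.dim, scramble=True, seed=rng)
        points = sampler.random(config.population_size)
    span = config.upper_bound - config.lower_bound
    return config.lower_bound + points * span


def cauchy_sample(rng: np.random.Generator) -> float:
    """One standard Cauchy(0, 1) variate via C = tan(pi * (U - 1/2)).

    U drawn uniform on (0, 1); boundary draws hitting the tangent
    singularity are redrawn.
    """
    u = rng.random()
    while u == 0.0:
        u = rng.random()
    return math.tan(math.pi * (u - 0.5))


def _cauchy_vector(rng: np.random.Generator, size: int) -> np.ndarray:
    u = rng.random(size)
    while np.any(u == 0.0):
        u[u == 0.0] = rng.random(np.count_nonzero(u == 0.0))
    return np.tan(np.pi * (u - 0.5))


def decay_factor(fes: int, max_fes: int) -> float:
    """Linear decay a = 1 - FEs/MaxFEs, from 1 down to 0."""
    if not 0 <= fes <= max_fes:
        raise ValueError(f"FEs must lie in [0, {max_fes}], got {fes}")
    return 1.0 - fes / max_fes


def random_replacement(
    pB_row: np.ndarray,
    gBest: np.ndarray,
    a: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cauchy-gated coordinate replacement of a personal best.

    Per dimension j a fresh Cauchy draw C gates the replacement: the output
    takes gBest_j when a < C and keeps pB_j otherwise.  Early in the run
    (a near 1) roughly a quarter of coordinates are replaced; by the end
    (a near 0) half are, pulling personal bests toward the incumbent.
    """
    if pB_row.shape != gBest.shape:
        raise ValueError("pB_row and gBest must have the same shape")
    c = _cauchy_vector(rng, pB_row.size)
    return np.where(a < c, gBest, pB_row)


def adaptive_weight(
    fes: int, max_fes: int, S: float, rng: np.random.Generator
) -> float:
    """Adaptive inertia weight omega = (1 - FEs/MaxFEs)**beta.

    beta = 1 - C1*S/MaxFEs with C1 a fresh standard Cauchy draw.  Guards:
    a zero base (budget exhausted) yields omega = 0, and omega is computed
    in log space and capped at 10 so heavy-tailed beta draws cannot
    overflow; velocity clamping bounds the dynamical effect regardless.
    """
    base = decay_factor(fes, max_fes)
    c1 = cauchy_sample(rng)
    beta = 1.0 - c1 * S / max_fes
    if base <= 0.0:
        return 0.0
    log_omega = beta * math.log(base)
    if log_omega >= math.log(10.0):
        return 10.0
    return math.exp(log_omega)


def update_S(S: float, global_best_improved: bool) -> float:
    """Adaptive scalar update: halved on a global-best improvement, else +1."""
    return S / 2.0 if global_best_improved else S + 1.0


def velocity_update(
    V_row: np.ndarray,
    X_row: np.ndarray,
    pB_row: np.ndarray,
    gBest: np.ndarray,
    omega: float,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inertia + cognitive + social velocity update, clamped to [-Vmax, Vmax].

    Fresh uniform draws are made per term and per dimension.
    """
    r1 = rng.random(V_row.size)
    r2 = rng.random(V_row.size)
    v = omega * V_row + config.c1 * r1 * (pB_row - X_row) + config.c2 * r2 * (gBest - X_row)
    return np.clip(v, -config.v_max, config.v_max)


def position_update(X_row: np.ndarray, V_row: np.ndarray, config: SwarmConfig) -> np.ndarray:
    """Move by the velocity and clamp back into the search box."""
    return np.clip(X_row + V_row, config.lower_bound, config.upper_bound)


def update_bests(state: SwarmState, index: int, fitness: float) -> SwarmState:
    """Strict-improvement update of personal and global bests.

    Ties keep the incumbent; evaluation accounting is the caller's job.
    """
    if fitness < state.personal_best_score[index]:
        state.personal_best_score[index] = fitness
        state.personal_best[index] = state.positions[index].copy()
    if fitness < state.global_best_score:
        state.global_best_score = fitness
        state.global_best = state.positions[index].copy()
    return state


def _check_compatible(objective: ObjectiveSpec, config: SwarmConfig) -> None:
    if objective.dim != config.dim:
        raise ValueError(
            f"objective dim {objective.dim} does not match config dim {config.dim}"
        )


def _evaluate_positions(
    objective: ObjectiveSpec, state: SwarmState, config: SwarmConfig, *, track_S: bool
) -> None:
    """Evaluate as many particles as the budget allows, updating bests.

    When ``track_S`` the adaptive scalar is updated after every evaluation
    according to whether that evaluation improved the global best.
    """
    n = state.positions.shape[0]
    budget_left = config.max_evaluations - state.evaluations_used
    for i in range(min(n, budget_left)):
        fitness = objective(state.positions[i])
        state.evaluations_used += 1
        improved = fitness < state.global_best_score
        update_bests(state, i, fitness)
        if track_S:
            state.adaptive_S = update_S(state.adaptive_S, improved)


def _velocity_position_pass(
    state: SwarmState, config: SwarmConfig, omega: float, rng: np.random.Generator
) -> None:
    n, dim = state.positions.shape
    r1 = rng.random((n, dim))
    r2 = rng.random((n, dim))
    v = (
        omega * state.velocities
        + config.c1 * r1 * (state.personal_best - state.positions)
        + config.c2 * r2 * (state.global_best - state.positions)
    )
    np.clip(v, -config.v_max, config.v_max, out=v)
    state.velocities = v
    state.positions = np.clip(
        state.positions + v, config.lower_bound, config.upper_bound
    )


def _init_state(X: np.ndarray, config: SwarmConfig) -> SwarmState:
    n, dim = X.shape
    return SwarmState(
        positions=np.clip(X, config.lower_bound, config.upper_bound),
        velocities=np.zeros((n, dim)),
        personal_best=X.copy(),
        personal_best_score=np.full(n, np.inf),
        global_best=X[0].copy(),
        global_best_score=np.inf,
        adaptive_S=config.s_init,
    )


def run_pso(objective: ObjectiveSpec, config: SwarmConfig) -> OptimizeResult:
    """Canonical particle swarm optimization.

    Each iteration evaluates every particle (clamped into the box), updates
    personal and global bests under strict improvement, then applies the
    velocity and position updates, until the evaluation budget is spent.
    """
    _check_compatible(objective, config)
    rng = np.random.default_rng(config.seed)
    state = _init_state(init_random_population(config, rng), config)
    trace: list[tuple[int, float]] = []

    while state.evaluations_used < config.max_evaluations:
        _evaluate_positions(objective, state, config, track_S=False)
        trace.append((state.evaluations_used, state.global_best_score))
        if state.evaluations_used >= config.max_evaluations:
            break
        _velocity_position_pass(state, config, omega=1.0, rng=rng)
        state.iteration += 1

    return OptimizeResult(
        best_position=state.global_best.copy(),
        best_score=state.global_best_score,
        trace=trace,
        evaluations_used=state.evaluations_used,
    )


def run_srwpso(objective: ObjectiveSpec, config: SwarmConfig) -> OptimizeResult:
    """SRWPSO: PSO boosted by the SOB, RRS and AWS strategies.

    Structure per iteration: a random-replacement pass over personal bests
    (each hybridized personal best is re-evaluated unconditionally and may
    temporarily degrade — only the global best is monotone), a single
    adaptive-weight update shared by the whole swarm, the velocity/position
    updates, and an evaluation pass that also drives the adaptive scalar S.
    With all three strategy flags off the dynamics reduce exactly to
    :func:`run_pso`.
    """
    _check_compatible(objective, config)
    rng = np.random.default_rng(config.seed)
    init = init_sobol_population if config.use_sobol else init_random_population
    state = _init_state(init(config, rng), config)
    trace: list[tuple[int, float]] = []

    # initial evaluation pass (no S tracking: S starts moving with the
    # main loop's evaluation pass)
    _evaluate_positions(objective, state, config, track_S=False)
    trace.append((state.evaluations_used, state.global_best_score))

    while state.evaluations_used < config.max_evaluations:
        if config.use_rrs:
            n = state.positions.shape[0]
            for i in range(n):
                if state.evaluations_used >= config.max_evaluations:
                    break
                a = decay_factor(state.evaluations_used, config.max_evaluations)
                hybrid = random_replacement(
                    state.personal_best[i], state.global_best, a, rng
                )
                hybrid = np.clip(hybrid, config.lower_bound, config.upper_bound)
                fitness = objective(hybrid)
                state.evaluations_used += 1
                # unconditional acceptance: the hybrid replaces the personal
                # best even when worse — this is the diversity injection
                state.personal_best[i] = hybrid
                state.personal_best_score[i] = fitness
                if fitness < state.global_best_score:
                    state.global_best_score = fitness
                    state.global_best = hybrid.copy()
            trace.append((state.evaluations_used, state.global_best_score))
            if state.evaluations_used >= config.max_evaluations:
                break

        omega = (
            adaptive_weight(
                state.evaluations_used, config.max_evaluations, state.adaptive_S, rng
            )
            if config.use_aws
            else 1.0
        )
        _velocity_position_pass(state, config, omega=omega, rng=rng)
        _evaluate_positions(objective, state, config, track_S=True)
        trace.append((state.evaluations_used, state.global_best_score))
        state.iteration += 1

    return OptimizeResult(
        best_position=state.global_best.copy(),
        best_score=state.global_best_score,
        trace=trace,
        evaluations_used=state.evaluations_used,
    )
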