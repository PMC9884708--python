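"""Binary SRWPSO (bSRWPSO) for subset-selection problems.

Each particle carries a dual representation: a continuous position in
[0, 1]^D driven by the SRWPSO dynamics, and a persistent binary mask that is
what the (lower-is-better) fitness function actually sees.  After every
continuous move, each mask bit is flipped with probability V(x_d), where
V(x) = |tanh(x)| is the V-shaped transfer applied to the continuous
coordinate: coordinates near 0 freeze their bit, coordinates pushed hard in
either direction make a flip near-certain.

Feature-selection runs are iteration-limited (default 50 iterations at
population 20) rather than evaluation-limited; the nominal evaluation
budget that the decaying strategy parameters need is derived as
iterations x evaluations-per-iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .swarm import (
    SwarmConfig,
    _cauchy_vector,
    adaptive_weight,
    decay_factor,
    init_random_population,
    init_sobol_population,
    update_S,
)

__all__ = ["BinaryResult", "v_transfer", "binarize_step", "run_bsrwpso"]


@dataclass
class BinaryResult:
    """Best mask found by a binary swarm run."""

    best_mask: np.ndarray
    best_fitness: float
    trace: list[tuple[int, float]] = field(default_factory=list)
    selected_count: int = 0


def v_transfer(x: float) -> float:
    """V-shaped transfer V(x) = |tanh(x)|, a flip probability in [0, 1)."""
    return float(np.abs(np.tanh(x)))


def binarize_step(
    mask: np.ndarray, continuous_position: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Advance a binary mask: flip each bit with probability V(x_d).

    A fresh uniform r is drawn per dimension; the bit is complemented when
    r < V(x_d) and kept otherwise, so a zero coordinate leaves its bit
    untouched.
    """
    if mask.shape != continuous_position.shape:
        raise ValueError("mask and continuous_position must have the same shape")
    r = rng.random(mask.size)
    flip = r < np.abs(np.tanh(continuous_position))
    return np.where(flip, 1 - mask, mask).astype(mask.dtype)


def _default_config(D: int) -> SwarmConfig:
    return SwarmConfig(
        dim=D,
        population_size=20,
        max_evaluations=10**9,  # placeholder; binary runs are iteration-limited
        lower_bound=0.0,
        upper_bound=1.0,
    )


def run_bsrwpso(
    fitness: Callable[[np.ndarray], float],
    D: int,
    config: Optional[SwarmConfig] = None,
    iterations: int = 50,
) -> BinaryResult:
    """Minimize a lower-is-better fitness over binary masks of length D.

    Continuous SRWPSO dynamics run on [0, 1]^D; personal and global bests
    store (mask, continuous position) pairs and all best-update comparisons
    use mask fitness.  The random-replacement gate of the continuous
    algorithm is applied per dimension jointly to the (coordinate, bit)
    pair, so the hybridized personal best stays a consistent pair.  Initial
    masks threshold the initial continuous positions at 0.5.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if config is None:
        config = _default_config(D)
    if config.dim != D:
        raise ValueError(f"config dim {config.dim} does not match D={D}")

    N = config.population_size
    evals_per_iter = 2 * N if config.use_rrs else N
    max_fes = N + iterations * evals_per_iter  # drives the decay terms

    rng = np.random.default_rng(config.seed)
    init = init_sobol_population if config.use_sobol else init_random_population
    X = np.clip(init(config, rng), 0.0, 1.0)
    V = np.zeros((N, D))
    masks = (X > 0.5).astype(np.int8)

    scores = np.empty(N)
    for i in range(N):
        scores[i] = float(fitness(masks[i]))
    fes = N

    pB_cont = X.copy()
    pB_mask = masks.copy()
    pB_score = scores.copy()
    g = int(np.argmin(scores))
    best_mask = masks[g].copy()
    best_cont = X[g].copy()
    best_score = float(scores[g])
    S = config.s_init
    trace: list[tuple[int, float]] = [(fes, best_score)]

    for _ in range(iterations):
        if config.use_rrs:
            for i in range(N):
                a = decay_factor(fes, max_fes)
                c = _cauchy_vector(rng, D)
                take = a < c
                hybrid_cont = np.where(take, best_cont, pB_cont[i])
                hybrid_mask = np.where(take, best_mask, pB_mask[i]).astype(np.int8)
                f = float(fitness(hybrid_mask))
                fes += 1
                pB_cont[i] = hybrid_cont
                pB_mask[i] = hybrid_mask
                pB_score[i] = f
                if f < best_score:
                    best_score = f
                    best_mask = hybrid_mask.copy()
                    best_cont = hybrid_cont.copy()
            trace.append((fes, best_score))

        omega = (
            adaptive_weight(fes, max_fes, S, rng) if config.use_aws else 1.0
        )
        r1 = rng.random((N, D))
        r2 = rng.random((N, D))
        V = (
            omega * V
            + config.c1 * r1 * (pB_cont - X)
            + config.c2 * r2 * (best_cont - X)
        )
        np.clip(V, -config.v_max, config.v_max, out=V)
        X = np.clip(X + V, 0.0, 1.0)

        for i in range(N):
            masks[i] = binarize_step(masks[i], X[i], rng)
            f = float(fitness(masks[i]))
            fes += 1
            improved = f < best_score
            if f < pB_score[i]:
                pB_score[i] = f
                pB_mask[i] = masks[i].copy()
                pB_cont[i] = X[i].copy()
            if improved:
                best_score = f
                best_mask = masks[i].copy()
                best_cont = X[i].copy()
            S = update_S(S, improved)
        trace.append((fes, best_score))

    return BinaryResult(
        best_mask=best_mask.astype(np.int8),
        best_fitness=best_score,
        trace=trace,
        selected_count=int(best_mask.sum()),
    )
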