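"""Bounded continuous test objectives for swarm optimizers.

The built-in suite provides the classic analytic base functions that the
CEC-style benchmark families are assembled from (sphere, elliptic, bent
cigar, discus, Rosenbrock, Ackley, Rastrigin, Griewank, Schwefel 1.2), each
defined on the box [-100, 100]^dim with known global minimum 0.  A generic
``shift_rotate`` wrapper composes any base objective with a user-supplied
shift vector, rotation matrix and bias, f(M (x - o)) + bias, which is how
shifted/rotated benchmark instances are constructed; users who need an
official benchmark instantiation can plug its data into the wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["ObjectiveSpec", "make_objective", "shift_rotate", "OBJECTIVE_NAMES"]


@dataclass(frozen=True)
class ObjectiveSpec:
    """A bounded continuous minimization objective.

    Parameters
    ----------
    name : str
        Identifier of the objective.
    dim : int
        Dimensionality of the search space.
    lower_bound, upper_bound : float
        Box constraints, applied in every dimension.
    evaluate : callable
        Pure function mapping a length-``dim`` vector to a scalar.
    known_optimum : float, optional
        Global minimum value, when documented.
    bias : float
        Additive offset already folded into ``evaluate``.
    """

    name: str
    dim: int
    evaluate: Callable[[np.ndarray], float]
    lower_bound: float = -100.0
    upper_bound: float = 100.0
    known_optimum: Optional[float] = None
    bias: float = 0.0
    minimizer: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be strictly below upper_bound")

    def __call__(self, x: np.ndarray) -> float:
        return float(self.evaluate(np.asarray(x, dtype=float)))


def _sphere(x: np.ndarray) -> float:
    return float(np.dot(x, x))


def _elliptic(x: np.ndarray) -> float:
    d = x.size
    # 0/0 exponent at d=1 resolves to weight 1 (continuity with the d->1 limit)
    exponents = np.linspace(0.0, 1.0, d) if d > 1 else np.array([0.0])
    return float(np.sum((10.0**6) ** exponents * x**2))


def _bent_cigar(x: np.ndarray) -> float:
    return float(x[0] ** 2 + 10.0**6 * np.dot(x[1:], x[1:]))


def _discus(x: np.ndarray) -> float:
    return float(10.0**6 * x[0] ** 2 + np.dot(x[1:], x[1:]))


def _rosenbrock(x: np.ndarray) -> float:
    if x.size == 1:
        return float((x[0] - 1.0) ** 2)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def _ackley(x: np.ndarray) -> float:
    d = x.size
    term1 = -20.0 * np.exp(-0.2 * np.sqrt(np.dot(x, x) / d))
    term2 = -np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
    return float(term1 + term2 + 20.0 + np.e)


def _rastrigin(x: np.ndarray) -> float:
    return float(np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def _griewank(x: np.ndarray) -> float:
    d = x.size
    return float(
        np.dot(x, x) / 4000.0 - np.prod(np.cos(x / np.sqrt(np.arange(1, d + 1)))) + 1.0
    )


def _schwefel(x: np.ndarray) -> float:
    # Schwefel problem 1.2: sum of squared prefix sums
    return float(np.sum(np.cumsum(x) ** 2))


_REGISTRY: dict[str, Callable[[np.ndarray], float]] = {
    "sphere": _sphere,
    "elliptic": _elliptic,
    "bent_cigar": _bent_cigar,
    "discus": _discus,
    "rosenbrock": _rosenbrock,
    "ackley": _ackley,
    "rastrigin": _rastrigin,
    "griewank": _griewank,
    "schwefel": _schwefel,
}

OBJECTIVE_NAMES = tuple(sorted(_REGISTRY))


def make_objective(name: str, dim: int) -> ObjectiveSpec:
    """Build a built-in objective on [-100, 100]^dim with known optimum 0.

    The documented minimizer is the origin for all functions except
    Rosenbrock, whose minimum sits at the all-ones point.
    """
    if name not in _REGISTRY:
        raise ValueError(
            f"unknown objective {name!r}; valid names: {', '.join(OBJECTIVE_NAMES)}"
        )
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    minimizer = np.ones(dim) if name == "rosenbrock" else np.zeros(dim)
    return ObjectiveSpec(
        name=name,
        dim=dim,
        evaluate=_REGISTRY[name],
        known_optimum=0.0,
        minimizer=minimizer,
    )


def shift_rotate(
    base: ObjectiveSpec,
    shift: np.ndarray,
    rotation: np.ndarray,
    bias: float = 0.0,
) -> ObjectiveSpec:
    """Compose ``base`` into f(M (x - o)) + bias.

    ``known_optimum`` carries over (plus bias) only when ``rotation`` is
    orthogonal, since only then is the rotated minimizer guaranteed to be
    reachable at ``shift + M^T minimizer``.
    """
    shift = np.asarray(shift, dtype=float)
    rotation = np.asarray(rotation, dtype=float)
    if shift.shape != (base.dim,):
        raise ValueError(f"shift must have length {base.dim}, got shape {shift.shape}")
    if rotation.shape != (base.dim, base.dim):
        raise ValueError(
            f"rotation must be {base.dim}x{base.dim}, got shape {rotation.shape}"
        )

    inner = base.evaluate

    def evaluate(x: np.ndarray) -> float:
        return float(inner(rotation @ (np.asarray(x, dtype=float) - shift)) + bias)

    orthogonal = np.allclose(rotation @ rotation.T, np.eye(base.dim), atol=1e-10)
    known = base.known_optimum + bias if (orthogonal and base.known_optimum is not None) else None
    minimizer = None
    if orthogonal and base.minimizer is not None:
        minimizer = shift + rotation.T @ base.minimizer
    return ObjectiveSpec(
        name=f"{base.name}_shifted_rotated",
        dim=base.dim,
        evaluate=evaluate,
        lower_bound=base.lower_bound,
        upper_bound=base.upper_bound,
        known_optimum=known,
        bias=bias,
        minimizer=minimizer,
    )
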