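"""Northern goshawk optimization (NGO) and its improved variant (INGO).

NGO is a two-phase population metaheuristic: a global "prey identification"
phase in which each hawk moves relative to a randomly chosen peer, and a
local "chase and escape" phase with a linearly shrinking attack radius
R = 0.02 (1 - t/T).  Every move is accepted greedily, so the best-so-far
fitness is monotonically non-increasing.

INGO layers three modifications on top:

1. cubic chaotic initialization x_{n+1} = rho x_n (1 - x_n^2), improving the
   coverage of the initial population;
2. a sine-cosine position rule replacing phase 1, blended by a cosine
   inertia factor that decays from omega_max toward the midpoint of
   [omega_min, omega_max] over the run;
3. a random differential perturbation of the incumbent best, guarding the
   late iterations against premature convergence.

Both variants are used here to tune the (gamma, sigma) hyperparameters of
the LSSVM regressor, and are exposed on standard benchmark functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "OptimizerConfig",
    "OptimizerRun",
    "cubic_map_sequence",
    "init_population",
    "ngo_phase1_update",
    "attack_radius",
    "ngo_phase2_update",
    "cosine_factor",
    "sine_cosine_update",
    "random_diff_perturbation",
    "optimize",
    "BENCHMARKS",
]

# defaults for the INGO ingredients; the chaos coefficient keeps the cubic
# map inside (0,1) since rho * max x(1-x^2) = rho * 2/(3*sqrt(3)) < 1
DEFAULT_RHO = 2.595
DEFAULT_OMEGA_MIN = 0.4
DEFAULT_OMEGA_MAX = 0.9


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box bounds of the decision vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size < 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(lo < hi):
            raise ValueError("lower must be elementwise below upper")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, X: np.ndarray) -> np.ndarray:
        return np.clip(X, self.lower, self.upper)


@dataclass(frozen=True)
class OptimizerConfig:
    pop_size: int = 30
    max_iter: int = 100
    variant: str = "ingo"
    rho: float = DEFAULT_RHO
    omega_min: float = DEFAULT_OMEGA_MIN
    omega_max: float = DEFAULT_OMEGA_MAX
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.variant not in ("ngo", "ingo"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0 <= self.omega_min < self.omega_max):
            raise ValueError("require 0 <= omega_min < omega_max")


@dataclass
class OptimizerRun:
    """Result of one optimization: incumbent and best-fitness trace."""

    best_x: np.ndarray
    best_f: float
    history: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_evals: int = 0


def cubic_map_sequence(x0: float, rho: float = DEFAULT_RHO, count: int = 1) -> np.ndarray:
    """Iterates of the cubic chaotic map x <- rho x (1 - x^2)."""
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie strictly inside (0, 1)")
    out = np.empty(count)
    x = x0
    for i in range(count):
        x = rho * x * (1.0 - x * x)
        out[i] = x
    return out


def init_population(space: SearchSpace, config: OptimizerConfig) -> np.ndarray:
    """Initial N x D positions: chaotic for ingo, uniform for ngo."""
    rng = np.random.default_rng(config.seed)
    N, D = config.pop_size, space.dim
    if config.variant == "ingo":
        unit = np.empty((N, D))
        for j in range(D):
            x0 = float(rng.uniform(0.05, 0.95))
            unit[:, j] = cubic_map_sequence(x0, config.rho, N)
    else:
        unit = rng.random((N, D))
    return space.lower + unit * (space.upper - space.lower)


def _evaluate(fitness: Callable[[np.ndarray], float], X: np.ndarray) -> np.ndarray:
    f = np.array([float(fitness(x)) for x in X])
    if not np.all(np.isfinite(f)):
        bad = X[int(np.argmax(~np.isfinite(f)))]
        raise ValueError(f"fitness is non-finite at {bad}")
    return f


def _greedy(
    pop: np.ndarray,
    fit: np.ndarray,
    cand: np.ndarray,
    fitness: Callable[[np.ndarray], float],
    space: SearchSpace,
) -> tuple[np.ndarray, np.ndarray, int]:
    cand = space.clip(cand)
    cf = _evaluate(fitness, cand)
    better = cf < fit
    pop = np.where(better[:, None], cand, pop)
    fit = np.where(better, cf, fit)
    return pop, fit, cand.shape[0]


def _select_prey(N: int, rng: np.random.Generator) -> np.ndarray:
    """One random peer index per individual, never itself."""
    return (np.arange(N) + rng.integers(1, N, size=N)) % N


def ngo_phase1_update(
    population: np.ndarray, fitnesses: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exploration candidates: move toward a better random prey, away otherwise.

    With prey p (a random other member), each coordinate moves by
    r (p - I x) when the prey is fitter, and by r (x - p) when it is not;
    r ~ U[0,1] and I in {1,2} are drawn per coordinate.
    """
    pop = np.atleast_2d(population)
    N, D = pop.shape
    if N < 2:
        raise ValueError("phase 1 needs at least two individuals")
    k = _select_prey(N, rng)
    prey = pop[k]
    prey_better = (fitnesses[k] < fitnesses)[:, None]
    r = rng.random((N, D))
    I = rng.integers(1, 3, size=(N, D))
    toward = pop + r * (prey - I * pop)
    away = pop + r * (pop - prey)
    return np.where(prey_better, toward, away)


def attack_radius(t: float, T: int) -> float:
    """Linearly decaying chase radius R = 0.02 (1 - t/T)."""
    if t < 0 or t > T:
        raise ValueError("require 0 <= t <= T")
    return 0.02 * (1.0 - t / T)


def ngo_phase2_update(
    population: np.ndarray,
    fitnesses: np.ndarray,
    t: float,
    T: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exploitation candidates x + R(t) (2r - 1) x, r ~ U[0,1] per coordinate."""
    pop = np.atleast_2d(population)
    R = attack_radius(t, T)
    r = rng.random(pop.shape)
    return pop + R * (2.0 * r - 1.0) * pop


def cosine_factor(
    t: float,
    T: int,
    omega_min: float = DEFAULT_OMEGA_MIN,
    omega_max: float = DEFAULT_OMEGA_MAX,
) -> float:
    """Inertia weight cos(pi t^3 / (3 T^3)) (omega_max - omega_min) + omega_min.

    Decays smoothly from omega_max at t = 0 to the midpoint of the range at
    t = T (the cosine argument never exceeds pi/3, so the factor stays
    positive and monotone non-increasing).
    """
    if t < 0 or t > T:
        raise ValueError("require 0 <= t <= T")
    return float(np.cos(np.pi * t**3 / (3.0 * T**3)) * (omega_max - omega_min) + omega_min)


def sine_cosine_update(
    population: np.ndarray,
    fitnesses: np.ndarray,
    omega: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sine-cosine exploration candidates blended by inertia weight omega.

    When the random prey is fitter:   (1-w) x + w sin(r1) |r2 p - x|
    otherwise:                        (1-w) x + w cos(r1) |x - r2 p|
    with r1 ~ U[0, 2 pi] and r2 ~ U[0, 2] per coordinate.
    """
    pop = np.atleast_2d(population)
    N, D = pop.shape
    if N < 2:
        raise ValueError("sine-cosine update needs at least two individuals")
    k = _select_prey(N, rng)
    prey = pop[k]
    prey_better = (fitnesses[k] < fitnesses)[:, None]
    r1 = rng.uniform(0.0, 2.0 * np.pi, size=(N, D))
    r2 = rng.uniform(0.0, 2.0, size=(N, D))
    toward = (1.0 - omega) * pop + omega * np.sin(r1) * np.abs(r2 * prey - pop)
    away = (1.0 - omega) * pop + omega * np.cos(r1) * np.abs(pop - r2 * prey)
    return np.where(prey_better, toward, away)


def random_diff_perturbation(
    best_x: np.ndarray,
    x_i: np.ndarray,
    x_rand: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Candidate r1 (best - x_i) + r2 (x_rand - x_i) with independent r draws."""
    best_x = np.asarray(best_x, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    x_rand = np.asarray(x_rand, dtype=float)
    r1 = rng.random(best_x.shape)
    r2 = rng.random(best_x.shape)
    return r1 * (best_x - x_i) + r2 * (x_rand - x_i)


def optimize(
    fitness: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig,
) -> OptimizerRun:
    """Minimize ``fitness`` over the box by NGO or INGO.

    Per iteration the ngo variant runs phases 1 and 2; the ingo variant runs
    the sine-cosine rule in place of phase 1, then phase 2, then one
    differential perturbation of the incumbent best (x_rand drawn uniformly
    from the population).  All candidates are clipped to the box and
    accepted greedily, so the returned history is non-increasing.  Fully
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    T = config.max_iter
    pop = init_population(space, config)
    fit = _evaluate(fitness, pop)
    n_evals = pop.shape[0]
    history = np.empty(T)

    for t in range(1, T + 1):
        if config.variant == "ngo":
            cand = ngo_phase1_update(pop, fit, rng)
        else:
            omega = cosine_factor(t, T, config.omega_min, config.omega_max)
            cand = sine_cosine_update(pop, fit, omega, rng)
        pop, fit, ne = _greedy(pop, fit, cand, fitness, space)
        n_evals += ne

        cand = ngo_phase2_update(pop, fit, t, T, rng)
        pop, fit, ne = _greedy(pop, fit, cand, fitness, space)
        n_evals += ne

        if config.variant == "ingo":
            i_best = int(np.argmin(fit))
            x_rand = pop[int(rng.integers(0, pop.shape[0]))]
            cand = random_diff_perturbation(pop[i_best], pop[i_best], x_rand, rng)
            cand = space.clip(cand)
            cf = float(fitness(cand))
            n_evals += 1
            if not np.isfinite(cf):
                raise ValueError(f"fitness is non-finite at {cand}")
            if cf < fit[i_best]:
                pop[i_best] = cand
                fit[i_best] = cf

        history[t - 1] = float(np.min(fit))

    i_best = int(np.argmin(fit))
    return OptimizerRun(
        best_x=pop[i_best].copy(),
        best_f=float(fit[i_best]),
        history=history,
        n_evals=n_evals,
    )


# --- benchmark registry -----------------------------------------------------

def sphere(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


#: name -> (function, canonical box half-width)
BENCHMARKS: dict[str, tuple[Callable[[np.ndarray], float], float]] = {
    "sphere": (sphere, 5.0),
    "rastrigin": (rastrigin, 5.12),
    "rosenbrock": (rosenbrock, 5.0),
}
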