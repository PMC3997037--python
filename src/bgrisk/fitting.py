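"""Behavioral parameter search by a simple genetic algorithm.

Task parameters (alpha, beta, learning rates) are fitted by minimising
the squared distance between simulated summary statistics and target
behavioral statistics.  Because the simulators are stochastic and
non-differentiable, a population-based evolutionary search is used:
tournament selection, uniform crossover, Gaussian mutation with a
sigma proportional to each parameter's range, and elitism.  All GA
settings are exposed in :class:`SearchConfig`; the defaults are
pragmatic artifact choices, not empirical claims.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = ["SearchConfig", "FitResult", "fit_parameters"]


@dataclass(frozen=True)
class SearchConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.7
    mutation_rate: float = 0.3
    mutation_sigma_frac: float = 0.1  # sigma as a fraction of each range
    tournament_k: int = 3
    elitism: int = 1


@dataclass
class FitResult:
    best: dict[str, float]
    best_loss: float
    trace: list[float]  # best loss per generation


def fit_parameters(
    objective: Callable[[Mapping[str, float]], float],
    bounds: Mapping[str, tuple[float, float]],
    search_config: SearchConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Minimise ``objective`` over box-bounded parameters.

    ``objective`` maps a parameter dict to a loss; ``bounds`` maps each
    parameter name to finite (low, high).  Candidates never leave the
    bounds (clipping after mutation).  Reproducible given ``seed``.
    """
    if not bounds:
        raise ValueError("bounds must name at least one parameter")
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names], dtype=float)
    hi = np.array([bounds[n][1] for n in names], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(lo < hi)):
        raise ValueError("bounds must be finite with low < high")
    cfg = search_config or SearchConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    span = hi - lo

    def evaluate(pop: np.ndarray) -> np.ndarray:
        return np.array(
            [objective(dict(zip(names, ind))) for ind in pop], dtype=float
        )

    pop = lo + rng.random((cfg.population_size, len(names))) * span
    loss = evaluate(pop)
    trace: list[float] = []
    for _ in range(cfg.generations):
        order = np.argsort(loss)
        trace.append(float(loss[order[0]]))
        nxt = [pop[order[i]].copy() for i in range(cfg.elitism)]
        while len(nxt) < cfg.population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size, cfg.tournament_k)
                parents.append(pop[contenders[np.argmin(loss[contenders])]])
            a, b = parents
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(len(names)) < 0.5
                child = np.where(mask, a, b)
            else:
                child = a.copy()
            mutate = rng.random(len(names)) < cfg.mutation_rate
            child = child + mutate * rng.normal(
                0.0, cfg.mutation_sigma_frac * span
            )
            nxt.append(np.clip(child, lo, hi))
        pop = np.array(nxt)
        loss = evaluate(pop)
    best_i = int(np.argmin(loss))
    trace.append(float(loss[best_i]))
    return FitResult(dict(zip(names, pop[best_i])), float(loss[best_i]), trace)
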