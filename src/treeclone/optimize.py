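"""Inverse fitting: genetic-algorithm minimization of the structural distance.

The objective simulates the growth model at a candidate parameter vector v
(with a *fixed* simulation seed, so the same v always produces the same
tree — a requirement for the optimizer to converge on a stochastic model),
extracts the configured feature tables, and returns the mean structural
distance against the target tables.

The genetic algorithm is integer-aware (some growth parameters, such as
the number of iterations, only take integer values), uses tournament
selection, intermediate crossover for real genes, uniform-reset mutation
for integer genes, elitism, and stops on a stall — a fixed number of
generations without improvement — or at a generation cap.  Parameters
carry two ranges: global lower/upper bounds that clip the whole search,
and an initial range (a subset) from which the starting population is
drawn; sequential refinement re-centers the initial range on a previous
best fit while keeping the global bounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .distance import DirectionSet, aggregate_distance, generate_directions
from .features import FeatureTable, branch_table, merge_tables, segment_table
from .qsm import Tree
from .sot import SOTParams, simulate

__all__ = [
    "ParameterSpec",
    "GAConfig",
    "FitResult",
    "extract_pairs",
    "objective",
    "fit",
    "distance_profile",
    "refine_specs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterSpec:
    """One free parameter of the fit: bounds, initial range, integrality."""

    name: str
    lower: float
    upper: float
    init_lower: Optional[float] = None
    init_upper: Optional[float] = None
    is_integer: bool = False
    group: str = ""

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        il = self.lower if self.init_lower is None else self.init_lower
        iu = self.upper if self.init_upper is None else self.init_upper
        if il < self.lower or iu > self.upper or not il <= iu:
            raise ValueError(f"{self.name}: initial range must lie inside the global bounds")
        object.__setattr__(self, "init_lower", il)
        object.__setattr__(self, "init_upper", iu)


@dataclass
class GAConfig:
    """Genetic-algorithm settings."""

    population: int = 40
    max_generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.15
    stall_generations: int = 10
    tournament: int = 3
    seed: int = 0


@dataclass
class FitResult:
    """Outcome of one GA run."""

    best_params: dict
    best_distance: float
    per_pair: dict
    trace_best: list
    trace_median: list
    n_evaluations: int
    ga_seed: int
    sim_seed: int
    model_params: Optional[dict] = None  # full parameter set incl. fixed values

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------- #
# objective
# ---------------------------------------------------------------------- #

def extract_pairs(
    tree: Tree, targets: Sequence[FeatureTable]
) -> list[tuple[FeatureTable, FeatureTable]]:
    """Extract from ``tree`` one table matching each target's kind/orders."""
    pairs = []
    for t in targets:
        if t.kind == "segment":
            um = segment_table(tree, t.orders)
        else:
            um = branch_table(tree, t.orders)
        pairs.append((um, t))
    return pairs


def objective(
    v: Sequence[float],
    names: Sequence[str],
    base_params: SOTParams,
    targets: Sequence[FeatureTable],
    dirs,
    sim_seed: int,
) -> float:
    """Mean structural distance of the model at parameter vector ``v``.

    Pure function of v for a fixed ``sim_seed``: the growth simulation is
    seeded identically at every call.  A simulation failure scores the
    worst possible distance (1.0) rather than aborting the fit.
    """
    try:
        params = base_params.with_values(**dict(zip(names, v)))
        tree = simulate(params, sim_seed)
        pairs = extract_pairs(tree, targets)
        return aggregate_distance(pairs, dirs).mean
    except Exception:
        logger.exception("objective evaluation failed; scoring worst distance")
        return 1.0


def _dirs_for_targets(targets: Sequence[FeatureTable], n_lines: int) -> dict[int, DirectionSet]:
    dims = {len(t.columns) for t in targets}
    return {d: generate_directions(d, n_lines) for d in dims}


# ---------------------------------------------------------------------- #
# genetic algorithm
# ---------------------------------------------------------------------- #

def _sample_initial(specs, rng, size) -> np.ndarray:
    pop = np.empty((size, len(specs)))
    for j, s in enumerate(specs):
        if s.is_integer:
            pop[:, j] = rng.integers(int(np.ceil(s.init_lower)), int(np.floor(s.init_upper)) + 1, size)
        else:
            pop[:, j] = rng.uniform(s.init_lower, s.init_upper, size)
    return pop


def _clip(specs, x: np.ndarray) -> np.ndarray:
    for j, s in enumerate(specs):
        x[j] = min(max(x[j], s.lower), s.upper)
        if s.is_integer:
            x[j] = round(x[j])
    return x


def fit(
    specs: Sequence[ParameterSpec],
    fun: Optional[Callable[[np.ndarray], float]] = None,
    ga: Optional[GAConfig] = None,
    *,
    base_params: Optional[SOTParams] = None,
    targets: Optional[Sequence[FeatureTable]] = None,
    n_lines: int = 1000,
    sim_seed: int = 0,
) -> FitResult:
    """Minimize an objective over the parameter specs with a GA.

    Either pass a surrogate objective ``fun(vector) -> value``, or pass
    ``base_params`` and target ``targets`` tables, in which case the
    structural-distance objective is built internally.  The best-so-far
    trace is monotone non-increasing (elitism).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("at least one free parameter is required")
    if all(s.upper - s.lower <= 0 for s in specs):
        raise ValueError("degenerate parameter specs: no search space")
    ga = ga or GAConfig()
    names = [s.name for s in specs]

    dirs = None
    if fun is None:
        if base_params is None or targets is None:
            raise ValueError("need either a surrogate objective or (base_params, targets)")
        dirs = _dirs_for_targets(targets, n_lines)

        def fun(x: np.ndarray) -> float:
            return objective(x, names, base_params, targets, dirs, sim_seed)

    rng = np.random.default_rng(ga.seed)
    pop = _sample_initial(specs, rng, ga.population)
    scores = np.array([fun(ind) for ind in pop])
    n_eval = ga.population

    trace_best, trace_median = [], []
    best_i = int(np.argmin(scores))
    best_x, best_f = pop[best_i].copy(), float(scores[best_i])
    stall = 0

    for gen in range(ga.max_generations):
        trace_best.append(best_f)
        trace_median.append(float(np.median(scores)))
        if stall >= ga.stall_generations:
            break

        new_pop = [best_x.copy()]  # elitism
        while len(new_pop) < ga.population:
            # tournament selection of two parents
            idx1 = rng.integers(0, ga.population, ga.tournament)
            idx2 = rng.integers(0, ga.population, ga.tournament)
            p1 = pop[idx1[np.argmin(scores[idx1])]]
            p2 = pop[idx2[np.argmin(scores[idx2])]]
            if rng.random() < ga.crossover_rate:
                u = rng.random(len(specs))
                child = p1 + u * (p2 - p1)
            else:
                child = p1.copy()
            for j, s in enumerate(specs):
                if rng.random() < ga.mutation_rate:
                    if s.is_integer:
                        child[j] = rng.integers(int(np.ceil(s.lower)), int(np.floor(s.upper)) + 1)
                    else:
                        child[j] = child[j] + rng.normal(0.0, 0.1 * (s.upper - s.lower))
            new_pop.append(_clip(specs, child))
        pop = np.array(new_pop)
        scores = np.array([fun(ind) for ind in pop])
        n_eval += ga.population

        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_f - 1e-15:
            best_f = float(scores[gen_best])
            best_x = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1

    trace_best.append(best_f)
    trace_median.append(float(np.median(scores)))

    per_pair: dict = {}
    model_params = None
    if base_params is not None and targets is not None and dirs is not None:
        params = base_params.with_values(**dict(zip(names, best_x)))
        pairs = extract_pairs(simulate(params, sim_seed), targets)
        per_pair = aggregate_distance(pairs, dirs).per_pair
        model_params = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(params).items()
        }

    best_params = {
        s.name: (int(round(x)) if s.is_integer else float(x))
        for s, x in zip(specs, best_x)
    }
    return FitResult(
        best_params=best_params,
        best_distance=best_f,
        per_pair=per_pair,
        trace_best=trace_best,
        trace_median=trace_median,
        n_evaluations=n_eval,
        ga_seed=ga.seed,
        sim_seed=sim_seed,
        model_params=model_params,
    )


def refine_specs(
    specs: Sequence[ParameterSpec], result: FitResult, width: float = 0.25
) -> list[ParameterSpec]:
    """Re-center initial ranges on a previous best fit (sequential refinement).

    Each spec keeps its global bounds; the initial range becomes a window
    of ``width`` times the global span around the previous best value.
    """
    out = []
    for s in specs:
        center = result.best_params[s.name]
        half = 0.5 * width * (s.upper - s.lower)
        out.append(
            ParameterSpec(
                name=s.name, lower=s.lower, upper=s.upper,
                init_lower=max(s.lower, center - half),
                init_upper=min(s.upper, center + half),
                is_integer=s.is_integer, group=s.group,
            )
        )
    return out


# ---------------------------------------------------------------------- #
# distance profiles (parameter scans)
# ---------------------------------------------------------------------- #

def distance_profile(
    base_params: SOTParams,
    param_name: str,
    values: Sequence,
    targets: Sequence[FeatureTable],
    n_reps: int = 100,
    seed_base: int = 0,
    n_lines: int = 1000,
) -> pd.DataFrame:
    """Distance distribution along one parameter (landscape scan).

    For each parameter value, ``n_reps`` trees are simulated with distinct
    seeds and scored against the targets; the returned frame has one row
    per (value, rep) with the distance, from which per-value medians give
    the profile line.
    """
    if param_name not in {f for g in SOTParams.GROUPS.values() for f in g}:
        raise KeyError(f"unknown growth parameter {param_name!r}")
    dirs = _dirs_for_targets(targets, n_lines)
    names = [param_name]
    rows = []
    for val in values:
        for r in range(n_reps):
            d = objective([val], names, base_params, targets, dirs, seed_base + r)
            rows.append((val, seed_base + r, d))
    return pd.DataFrame(rows, columns=["value", "seed", "distance"])
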