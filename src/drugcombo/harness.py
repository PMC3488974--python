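"""Seeded closed-loop trials and Monte-Carlo benchmark aggregation.

A *trial* starts from a uniformly random combination and iterates a search
algorithm until it visits a *potent* combination -- one whose true normalized
response reaches the success threshold (default 0.95, i.e. within 5% of the
grid optimum) -- or exhausts its iteration budget. A *benchmark* repeats the
trial many times with independent sub-seeds and reports the success rate and
the mean experimental effort of the successful trials: distinct combinations
tested (the cost proxy under type-A revisits) and iterations (the cost proxy
under type-B re-measurement).
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .algorithms import ALGORITHMS, init_state, search_step
from .oracle import EvaluationOracle, NoiseModel
from .surfaces import ResponseSurface, builtin_surface

__all__ = [
    "ExperimentConfig",
    "TrialResult",
    "BenchmarkSummary",
    "default_budget",
    "run_trial",
    "run_benchmark",
    "compare_table",
]


def default_budget(n_drugs: int, grid_size: int) -> int:
    """Iteration budget used by the benchmarks.

    Two drugs: twice the number of possible combinations. Three to six
    drugs: 1,000 / 2,000 / 3,000 / 4,000 iterations; beyond six the linear
    rule ``1000 (N - 2)`` extends the sequence.
    """
    if n_drugs < 2:
        raise ValueError("default budgets are defined for 2 or more drugs")
    if n_drugs == 2:
        return 2 * int(grid_size)
    return 1000 * (n_drugs - 2)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full specification of one Monte-Carlo benchmark."""

    surface: Union[str, ResponseSurface]
    algorithm: str = "aru"
    alpha: float = 1.0
    noise_u: float = 0.0
    strategy: str = "A"
    n_trials: int = 5000
    success_threshold: float = 0.95
    budget: Optional[int] = None  # None -> default_budget
    seed: int = 0
    edge_mode: str = "clamp"
    drug_order: str = "random"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not 0.0 < self.success_threshold <= 1.0:
            raise ValueError("success_threshold must lie in (0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.budget is not None and self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.strategy not in ("A", "B"):
            raise ValueError("strategy must be 'A' or 'B'")
        if self.noise_u < 0:
            raise ValueError("noise_u must be >= 0")

    def resolve_surface(self) -> ResponseSurface:
        if isinstance(self.surface, ResponseSurface):
            return self.surface
        return builtin_surface(self.surface)

    def resolve_budget(self, surface: ResponseSurface) -> int:
        if self.budget is not None:
            return self.budget
        return default_budget(surface.grid.n_drugs, surface.grid.size)


@dataclass(frozen=True)
class TrialResult:
    """Outcome of a single closed-loop trial."""

    success: bool
    iterations_to_success: Optional[int]
    unique_combinations_to_success: Optional[int]
    best_true_response: float
    initial_levels: tuple
    trial_index: int


@dataclass
class BenchmarkSummary:
    """Monte-Carlo aggregates over one benchmark's trials.

    Effort means are conditional on success: failed trials contribute to the
    success rate only.
    """

    config: ExperimentConfig
    n_trials: int
    n_success: int
    success_rate: float
    success_rate_se: float
    mean_unique_combinations: Optional[float]
    mean_iterations: Optional[float]
    iterations_dist: np.ndarray = field(repr=False)
    unique_dist: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        cfg = self.config
        return {
            "surface": cfg.surface if isinstance(cfg.surface, str) else cfg.surface.name,
            "algorithm": cfg.algorithm,
            "alpha": cfg.alpha,
            "noise_u": cfg.noise_u,
            "strategy": cfg.strategy,
            "n_trials": self.n_trials,
            "success_rate": self.success_rate,
            "success_rate_se": self.success_rate_se,
            "mean_unique_combinations": self.mean_unique_combinations,
            "mean_iterations": self.mean_iterations,
            "seed": cfg.seed,
        }

    def export_distributions(self, path) -> None:
        """Write per-successful-trial effort distributions as TSV."""
        df = pd.DataFrame(
            {
                "iterations_to_success": self.iterations_dist,
                "unique_combinations_to_success": self.unique_dist,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    def export_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _trial_seed(master_seed: int, trial_index: int) -> np.random.SeedSequence:
    # counter-style derivation: trial k is reproducible in isolation
    return np.random.SeedSequence([int(master_seed), int(trial_index)])


def run_trial(
    config: ExperimentConfig,
    trial_index: int = 0,
    surface: ResponseSurface | None = None,
    trace: bool = False,
    return_oracle: bool = False,
):
    """Run one fully reproducible closed-loop trial.

    Separate RNG substreams drive the algorithm's decisions and the
    measurement noise, so type-A/type-B comparisons at the same sub-seed are
    paired. The initial observation is iteration 0; a potent start therefore
    succeeds with 0 iterations and 1 unique combination.
    """
    if surface is None:
        surface = config.resolve_surface()
    budget = config.resolve_budget(surface)
    algo_ss, noise_ss = _trial_seed(config.seed, trial_index).spawn(2)
    rng_algo = np.random.default_rng(algo_ss)
    oracle = EvaluationOracle(
        surface,
        NoiseModel(config.noise_u, np.random.default_rng(noise_ss)),
        strategy=config.strategy,
    )
    start = surface.grid.random_levels(rng_algo)
    f0 = oracle.observe(start)
    best_true = oracle.log[-1][2]
    success = best_true >= config.success_threshold
    iterations = 0 if success else None
    unique = 1 if success else None
    if not success:
        state = init_state(
            config.algorithm,
            surface.grid.shape,
            config.alpha,
            rng_algo,
            start,
            f0,
            edge_mode=config.edge_mode,
            drug_order=config.drug_order,
            trace=trace,
        )
        for it in range(1, budget + 1):
            search_step(state, oracle)
            true = oracle.log[-1][2]
            if true > best_true:
                best_true = true
            if true >= config.success_threshold:
                success = True
                iterations = it
                unique = oracle.unique_combinations
                break
    result = TrialResult(
        success=success,
        iterations_to_success=iterations,
        unique_combinations_to_success=unique,
        best_true_response=best_true,
        initial_levels=start,
        trial_index=trial_index,
    )
    if return_oracle:
        return result, oracle
    return result


def run_benchmark(config: ExperimentConfig, progress: bool = False) -> BenchmarkSummary:
    """Run ``config.n_trials`` independent trials and aggregate.

    Identical (config, seed) pairs yield bit-identical summaries.
    """
    surface = config.resolve_surface()
    successes = 0
    iters: list = []
    uniques: list = []
    for k in range(config.n_trials):
        res = run_trial(config, trial_index=k, surface=surface)
        if res.success:
            successes += 1
            iters.append(res.iterations_to_success)
            uniques.append(res.unique_combinations_to_success)
        if progress and (k + 1) % 1000 == 0:
            print(
                f"[drugcombo] {config.algorithm} on "
                f"{surface.name}: {k + 1}/{config.n_trials} trials",
                file=sys.stderr,
            )
    p = successes / config.n_trials
    se = float(np.sqrt(p * (1.0 - p) / config.n_trials))
    return BenchmarkSummary(
        config=config,
        n_trials=config.n_trials,
        n_success=successes,
        success_rate=p,
        success_rate_se=se,
        mean_unique_combinations=float(np.mean(uniques)) if uniques else None,
        mean_iterations=float(np.mean(iters)) if iters else None,
        iterations_dist=np.asarray(iters, dtype=int),
        unique_dist=np.asarray(uniques, dtype=int),
    )


def _effort(summary: BenchmarkSummary) -> Optional[float]:
    # experimental-cost column: unique combinations for noiseless/type-A,
    # iterations when every visit re-measures (type-B)
    if summary.config.strategy == "B" and summary.config.noise_u > 0:
        return summary.mean_iterations
    return summary.mean_unique_combinations


def compare_table(
    configs: Sequence[ExperimentConfig], progress: bool = False
) -> pd.DataFrame:
    """Run several benchmarks and lay them out as one comparison table.

    Rows are (surface, noise level, strategy); columns per algorithm carry
    the success rate (%) and the mean effort of successful trials (unique
    combinations for noiseless/type-A rows, iterations for noisy type-B
    rows). All configs mapping to one row must share a grid.
    """
    if len(configs) == 0:
        raise ValueError("need at least one experiment config")
    summaries = [run_benchmark(cfg, progress=progress) for cfg in configs]
    rows: dict = {}
    row_grid: dict = {}
    for s in summaries:
        surf = s.config.resolve_surface()
        key = (surf.name, s.config.noise_u, s.config.strategy)
        if key in row_grid and row_grid[key] is not surf.grid:
            raise ValueError(f"mixed grids in table row {key}")
        row_grid[key] = surf.grid
        cells = rows.setdefault(key, {})
        label = s.config.algorithm
        cells[f"{label} success rate (%)"] = 100.0 * s.success_rate
        cells[f"{label} effort"] = _effort(s)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(
        df.index, names=["surface", "noise_u", "strategy"]
    )
    return df.sort_index()
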