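"""Measurement channel between a search algorithm and a response surface.

Real drug responses are estimated experimentally, so each evaluation carries
measurement noise: the observed response is ``f_obs = f_true + eta`` with
``eta`` i.i.d. uniform on ``(-u, u)``. Two revisit strategies are supported:

* **type A** -- a previously tested combination is not re-measured; the cached
  observation is reused (saves experiments, but clings to past noise);
* **type B** -- every visit re-measures, drawing fresh noise.

The oracle also does the bookkeeping the benchmarks report: total
evaluations, distinct combinations tested, and the full visit log.
"""

from __future__ import annotations

import csv
from typing import Sequence

import numpy as np

from .surfaces import GridError, ResponseSurface

__all__ = ["NoiseModel", "EvaluationOracle"]


class NoiseModel:
    """Additive uniform measurement noise ``eta ~ U(-u, u)``.

    ``u = 0`` is noiseless and consumes no random numbers, so noiseless runs
    are invariant to the revisit strategy.
    """

    def __init__(self, u: float, rng: np.random.Generator | None = None) -> None:
        if u < 0:
            raise ValueError("noise half-width u must be >= 0")
        self.u = float(u)
        self.rng = rng if rng is not None else np.random.default_rng()

    def draw(self, size=None):
        if self.u == 0.0:
            return 0.0 if size is None else np.zeros(size)
        return self.rng.uniform(-self.u, self.u, size=size)


class EvaluationOracle:
    """Noisy, optionally caching view of a response surface.

    Every :meth:`observe` call appends to the visit log. Under strategy A a
    revisit returns the cached observation and does not count as a new
    evaluation; under strategy B it draws fresh noise and does.
    """

    def __init__(
        self,
        surface: ResponseSurface,
        noise: NoiseModel | None = None,
        strategy: str = "A",
    ) -> None:
        if strategy not in ("A", "B"):
            raise ValueError("strategy must be 'A' or 'B'")
        self.surface = surface
        self.noise = noise if noise is not None else NoiseModel(0.0)
        self.strategy = strategy
        self.cache: dict = {}
        self.total_evaluations = 0
        self._seen: set = set()
        self.log: list = []  # (levels, observed, true)

    @property
    def unique_combinations(self) -> int:
        """Number of distinct combinations ever queried."""
        return len(self._seen)

    def true_response(self, levels: Sequence[int]) -> float:
        return self.surface.response(levels)

    def observe(self, levels: Sequence[int]) -> float:
        """Measure the response at a combination, per the revisit strategy.

        Observed values are *not* clipped to [0, 1]: noise may push them
        slightly outside, and downstream reward probabilities are capped
        instead.
        """
        levels = self.surface.grid.validate_levels(levels)
        true = float(self.surface.table[levels])
        if self.strategy == "A":
            if levels in self.cache:
                observed = self.cache[levels]
            else:
                observed = true + float(self.noise.draw())
                self.cache[levels] = observed
                self.total_evaluations += 1
        else:
            observed = true + float(self.noise.draw())
            self.total_evaluations += 1
        self._seen.add(levels)
        self.log.append((levels, observed, true))
        return observed

    def unique_count_until(self, stop_index: int) -> int:
        """Distinct combinations among the first ``stop_index`` log entries."""
        if not 0 <= stop_index <= len(self.log):
            raise GridError(
                f"stop_index {stop_index} outside [0, {len(self.log)}]"
            )
        return len({entry[0] for entry in self.log[:stop_index]})

    def export_log_tsv(self, path) -> None:
        """Write the visit log as TSV: iteration, levels, concentrations, observed, true."""
        grid = self.surface.grid
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["iteration", "levels", "concentrations", "observed", "true"])
            for i, (levels, observed, true) in enumerate(self.log):
                conc = grid.concentrations(levels)
                writer.writerow(
                    [
                        i,
                        ",".join(map(str, levels)),
                        ",".join(f"{c:g}" for c in conc),
                        f"{observed:.10g}",
                        f"{true:.10g}",
                    ]
                )
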