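"""Per-step update logic of the stochastic search algorithms.

Four closed-loop searches over a discrete concentration grid are implemented,
all proposing single-level moves per drug per step:

* **Gur Game** (simultaneous or sequential): a fixed finite-state automaton.
  Each drug is *rewarded* (moved away from a fixed per-drug reference
  concentration, the median of its set) with probability equal to the current
  observed response, else *penalized* (moved toward the reference).
* **Informed single-pair search** (``enhanced``): updates one drug at a time;
  the beneficial direction is inferred from the response change of that
  drug's last single-level move, and taken with probability
  ``g = (1 + alpha * max(f, f')) / 2``.
* **Adaptive reference update (ARU)**: compares the current observation with
  a *reference* combination -- initially the start point, thereafter the most
  recent local maximum passed along the visit trajectory -- and steps in the
  direction of the virtual slope between the two with probability
  ``g = (1 + alpha * max(f(x^c), f(x^ref))) / 2``. When the reference carries
  no direction information for the chosen drug (coincident levels or exactly
  equal responses), the drug's own last single-level move supplies the
  direction instead, so the search keeps using the most recent informative
  observations rather than moving blindly.

``alpha = 0`` turns every algorithm's informed choice into a symmetric
random walk; ``alpha = 1`` weights past observations maximally.

Sequential algorithms pick the drug to update uniformly at random by default
(``drug_order="random"``). Strict round-robin is available, but together
with moves that always change exactly one level it freezes the joint
level-parity pattern of the walk, leaving whole parity classes of the grid
unreachable from some starts; random selection has no such invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .oracle import EvaluationOracle

__all__ = [
    "ALGORITHMS",
    "SearchState",
    "reward_probability",
    "gur_reward",
    "gur_penalize",
    "gur_step",
    "informed_direction",
    "enhanced_step",
    "aru_step",
    "update_reference",
    "init_state",
    "search_step",
]

ALGORITHMS = ("gur_simultaneous", "gur_sequential", "enhanced", "aru")


def reward_probability(f1: float, f2: float, alpha: float) -> float:
    """Probability of moving in the predicted beneficial direction.

    ``g = min(1, (1 + alpha * max(f1, f2)) / 2)``; always >= 0.5, so the
    informed direction is never less likely than its opposite. The cap
    handles noisy observations slightly above 1.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return min(1.0, 0.5 * (1.0 + alpha * max(f1, f2)))


def _random_sign(rng: np.random.Generator) -> int:
    return 1 if rng.random() < 0.5 else -1


def _random_neighbor(k: int, m: int, rng: np.random.Generator) -> int:
    """Uniformly random feasible one-level move from ``k`` on ``{0..m-1}``."""
    if k == 0:
        return 1
    if k == m - 1:
        return m - 2
    return k + _random_sign(rng)


def _check_gur_indices(k: int, ref_k: int, m: int) -> None:
    if not (0 <= k <= m - 1 and 0 <= ref_k <= m - 1):
        raise IndexError(f"level indices (k={k}, ref={ref_k}) outside [0, {m - 1}]")


def gur_reward(k: int, ref_k: int, m: int, rng: np.random.Generator) -> int:
    """Rewarded Gur Game move: one level further away from the reference.

    Clamped at the grid edges. ``k == ref_k`` is not covered by the automaton
    and resolves to a uniformly random feasible neighbor.
    """
    _check_gur_indices(k, ref_k, m)
    if k > ref_k:
        return k + 1 if k < m - 1 else k
    if k < ref_k:
        return k - 1 if k > 0 else k
    return _random_neighbor(k, m, rng)


def gur_penalize(k: int, ref_k: int, m: int, rng: np.random.Generator) -> int:
    """Penalized Gur Game move: one level toward the reference."""
    _check_gur_indices(k, ref_k, m)
    if k > ref_k:
        return k - 1
    if k < ref_k:
        return k + 1
    return _random_neighbor(k, m, rng)


def informed_direction(level1: int, level2: int, f1: float, f2: float) -> int:
    """Beneficial concentration-update direction from two observed points.

    Returns the sign of the virtual slope ``(f2 - f1) / (level2 - level1)``
    between ``(level1, f1)`` and ``(level2, f2)``: +1 means increasing the
    drug's concentration looks beneficial, -1 decreasing. Returns 0 (a tie,
    for the caller to resolve) when the responses are exactly equal or the
    levels coincide.
    """
    if level1 == level2 or f1 == f2:
        return 0
    slope = (f2 - f1) / (level2 - level1)
    return 1 if slope > 0 else -1


@dataclass
class SearchState:
    """Mutable per-trial state shared by all algorithms.

    Only the fields an algorithm needs are populated: ``reference`` and
    ``tail`` for ARU, ``memory`` for the informed single-pair search,
    ``gur_reference`` for the Gur Game.
    """

    algorithm: str
    shape: tuple
    alpha: float
    rng: np.random.Generator
    current: tuple
    current_f: float
    edge_mode: str = "clamp"
    drug_order: str = "random"
    reference: Optional[tuple] = None
    reference_f: Optional[float] = None
    memory: list = field(default_factory=list)  # per drug: (k_old, k_new, f_old, f_new)
    tail: list = field(default_factory=list)  # last <= 2 (levels, observed f)
    next_drug: int = 0
    gur_reference: Optional[tuple] = None
    trace: Optional[list] = None  # optional (drug, direction, rewarded, reference)

    def select_drug(self) -> int:
        if self.drug_order == "random":
            return int(self.rng.integers(0, len(self.shape)))
        n = self.next_drug
        self.next_drug = (n + 1) % len(self.shape)
        return n


def init_state(
    algorithm: str,
    shape: Sequence[int],
    alpha: float,
    rng: np.random.Generator,
    start: Sequence[int],
    start_f: float,
    edge_mode: str = "clamp",
    drug_order: str = "random",
    trace: bool = False,
) -> SearchState:
    """Initialize search state at an observed start combination.

    ``edge_mode`` governs moves prescribed off the grid for the sequential
    adaptive algorithms: ``clamp`` (default) keeps the level unchanged, like
    the Gur automaton; ``reflect`` moves one level inward instead. Clamping
    matters beyond avoiding waste: with reflection every iteration flips
    exactly one coordinate's parity in a fixed round-robin order, which
    confines the walk to a strict subset of joint level-parity classes and
    makes some combinations unreachable from some starts.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if edge_mode not in ("reflect", "clamp"):
        raise ValueError("edge_mode must be 'reflect' or 'clamp'")
    if drug_order not in ("random", "roundrobin"):
        raise ValueError("drug_order must be 'random' or 'roundrobin'")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    shape = tuple(int(m) for m in shape)
    start = tuple(int(k) for k in start)
    state = SearchState(
        algorithm=algorithm,
        shape=shape,
        alpha=alpha,
        rng=rng,
        current=start,
        current_f=float(start_f),
        edge_mode=edge_mode,
        drug_order=drug_order,
    )
    n = len(shape)
    if algorithm == "aru":
        # the reference starts at the trial's initial combination
        state.reference = start
        state.reference_f = float(start_f)
        state.tail = [(start, float(start_f))]
        state.memory = [None] * n
    elif algorithm == "enhanced":
        state.memory = [None] * n
    else:
        state.gur_reference = tuple((m - 1) // 2 for m in shape)
    if trace:
        state.trace = []
    return state


def _apply_move(k: int, direction: int, m: int, edge_mode: str) -> int:
    new_k = k + direction
    if 0 <= new_k < m:
        return new_k
    if edge_mode == "reflect":
        return k - direction
    return k  # clamp: stay put


def gur_step(state: SearchState, oracle: EvaluationOracle, mode: str | None = None) -> tuple:
    """One Gur Game iteration; returns the newly observed combination.

    Simultaneous mode moves every drug using the same current response and
    one independent uniform draw per drug; sequential mode moves a single
    selected drug. Edge handling is the automaton's own clamping.
    """
    if mode is None:
        mode = "simultaneous" if state.algorithm == "gur_simultaneous" else "sequential"
    rng = state.rng
    f = state.current_f
    ref = state.gur_reference
    new = list(state.current)
    if mode == "simultaneous":
        drugs = range(len(state.shape))
    else:
        drugs = (state.select_drug(),)
    for n in drugs:
        r = rng.random()
        if f > r:
            new[n] = gur_reward(new[n], ref[n], state.shape[n], rng)
            rewarded = True
        else:
            new[n] = gur_penalize(new[n], ref[n], state.shape[n], rng)
            rewarded = False
        if state.trace is not None:
            state.trace.append((n, new[n] - state.current[n], rewarded, ref))
    new = tuple(new)
    state.current_f = oracle.observe(new)
    state.current = new
    return new


def enhanced_step(state: SearchState, oracle: EvaluationOracle) -> tuple:
    """One iteration of the informed single-pair search.

    The first update of each drug has no memory pair and probes a uniformly
    random direction; afterwards the drug's last single-level move supplies
    the beneficial direction and the reward probability.
    """
    rng = state.rng
    n = state.select_drug()
    mem = state.memory[n]
    rewarded = None
    if mem is None:
        direction = _random_sign(rng)
    else:
        k_old, k_new, f_old, f_new = mem
        beneficial = informed_direction(k_old, k_new, f_old, f_new)
        if beneficial == 0:
            beneficial = _random_sign(rng)
        g = reward_probability(f_old, f_new, state.alpha)
        rewarded = g > rng.random()
        direction = beneficial if rewarded else -beneficial
    k = state.current[n]
    new_k = _apply_move(k, direction, state.shape[n], state.edge_mode)
    new = state.current[:n] + (new_k,) + state.current[n + 1 :]
    f_obs = oracle.observe(new)
    state.memory[n] = (k, new_k, state.current_f, f_obs)
    if state.trace is not None:
        state.trace.append((n, new_k - k, rewarded, None))
    state.current = new
    state.current_f = f_obs
    return new


def update_reference(state: SearchState, new_levels: tuple, new_f: float) -> None:
    """Adopt the just-passed trajectory-local maximum as the new reference.

    With the last three observed responses ``f(t-2), f(t-1), f(t)`` along the
    visit trajectory, the middle point becomes the reference iff it exceeds
    both neighbors strictly. Fewer than three observations: no-op.
    """
    tail = state.tail
    if len(tail) == 2:
        (_, f_prev2), (levels_prev, f_prev) = tail
        if f_prev > f_prev2 and f_prev > new_f:
            state.reference = levels_prev
            state.reference_f = f_prev
        tail.pop(0)
    tail.append((new_levels, new_f))


def aru_step(state: SearchState, oracle: EvaluationOracle) -> tuple:
    """One ARU iteration (one drug updated).

    The beneficial direction for drug ``n`` is the sign of the virtual slope
    between ``(x_n^c, f(x^c))`` and ``(x_n^ref, f(x^ref))``, taken with
    probability ``g(f(x^c), f(x^ref))``. When the reference comparison is
    uninformative for that drug -- its level coincides with the reference's,
    or the responses are exactly equal -- the drug's last single-level move
    supplies direction and reward probability instead (the single-pair
    rule), keeping the update anchored to the most recent informative
    observations; with no memory either, the direction is a random probe.
    After observing the new combination the reference is refreshed if the
    trajectory just passed a local maximum.
    """
    rng = state.rng
    n = state.select_drug()
    beneficial = informed_direction(
        state.current[n], state.reference[n], state.current_f, state.reference_f
    )
    g = reward_probability(state.current_f, state.reference_f, state.alpha)
    if beneficial == 0 and state.memory[n] is not None:
        k_old, k_new, f_old, f_new = state.memory[n]
        beneficial = informed_direction(k_old, k_new, f_old, f_new)
        g = reward_probability(f_old, f_new, state.alpha)
    if beneficial == 0:
        beneficial = _random_sign(rng)
    rewarded = g > rng.random()
    direction = beneficial if rewarded else -beneficial
    k = state.current[n]
    new_k = _apply_move(k, direction, state.shape[n], state.edge_mode)
    new = state.current[:n] + (new_k,) + state.current[n + 1 :]
    f_obs = oracle.observe(new)
    state.memory[n] = (k, new_k, state.current_f, f_obs)
    if state.trace is not None:
        state.trace.append((n, new_k - k, rewarded, state.reference))
    update_reference(state, new, f_obs)
    state.current = new
    state.current_f = f_obs
    return new


def search_step(state: SearchState, oracle: EvaluationOracle) -> tuple:
    """Dispatch one iteration of the state's algorithm."""
    if state.algorithm in ("gur_simultaneous", "gur_sequential"):
        return gur_step(state, oracle)
    if state.algorithm == "enhanced":
        return enhanced_step(state, oracle)
    return aru_step(state, oracle)
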