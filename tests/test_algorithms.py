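import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from drugcombo import (
    EvaluationOracle,
    NoiseModel,
    SearchState,
    builtin_surface,
    gur_penalize,
    gur_reward,
    informed_direction,
    init_state,
    reward_probability,
    search_step,
    update_reference,
)


class TestRewardProbability:
    @pytest.mark.parametrize(
        "f1,f2,alpha,expected",
        [
            (0.5, 0.3, 1.0, 0.75),
            (0.9, 0.1, 0.0, 0.5),
            (0.0, 0.0, 0.0, 0.5),
            (1.0, 1.0, 1.0, 1.0),
            (1.05, 0.9, 1.0, 1.0),  # noisy observation above 1: capped
        ],
    )
    def test_values(self, f1, f2, alpha, expected):
        assert reward_probability(f1, f2, alpha) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha", [-0.1, 1.1])
    def test_alpha_outside_unit_interval_rejected(self, alpha):
        with pytest.raises(ValueError):
            reward_probability(0.5, 0.5, alpha)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    def test_bounded_between_half_and_one(self, f1, f2, alpha):
        g = reward_probability(f1, f2, alpha)
        assert 0.5 <= g <= 1.0


def enumerate_gur(k, ref, m, rewarded):
    """Independent enumeration of the Gur automaton's moves.

    Returns the set of possible next levels with their probabilities.
    """
    if k > ref:
        if rewarded:
            return {min(k + 1, m - 1): 1.0}
        return {k - 1: 1.0}
    if k < ref:
        if rewarded:
            return {max(k - 1, 0): 1.0}
        return {k + 1: 1.0}
    # at the reference: uniformly random feasible neighbor either way
    neighbors = [x for x in (k - 1, k + 1) if 0 <= x < m]
    return {x: 1.0 / len(neighbors) for x in neighbors}


class TestGurAutomaton:
    def test_full_truth_table_small_grids(self, rng):
        for m in range(2, 6):
            for k, ref in itertools.product(range(m), range(m)):
                for rewarded, fn in [(True, gur_reward), (False, gur_penalize)]:
                    expected = enumerate_gur(k, ref, m, rewarded)
                    if len(expected) == 1:
                        (lvl,) = expected
                        assert fn(k, ref, m, rng) == lvl, (m, k, ref, rewarded)
                    else:
                        outcomes = {fn(k, ref, m, rng) for _ in range(60)}
                        assert outcomes == set(expected), (m, k, ref, rewarded)

    def test_tie_moves_each_side_half_the_time(self, rng):
        n = 4000
        ups = sum(gur_reward(2, 2, 5, rng) == 3 for _ in range(n))
        # binomial 3-sigma band around 1/2
        assert abs(ups / n - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_out_of_range_indices_rejected(self, rng):
        with pytest.raises(IndexError):
            gur_reward(5, 2, 5, rng)
        with pytest.raises(IndexError):
            gur_penalize(0, 7, 5, rng)


class TestInformedDirection:
    @pytest.mark.parametrize(
        "l1,l2,f1,f2,expected",
        [
            (1, 4, 0.2, 0.7, +1),   # lower level worse: increase
            (6, 4, 0.7, 0.2, +1),   # higher level better: increase
            (1, 4, 0.9, 0.2, -1),   # lower level better: decrease
            (6, 4, 0.2, 0.9, -1),   # higher level worse: decrease
            (3, 4, 0.5, 0.5, 0),    # equal responses: tie
            (4, 4, 0.2, 0.9, 0),    # coincident levels: tie
        ],
    )
    def test_sign_patterns(self, l1, l2, f1, f2, expected):
        assert informed_direction(l1, l2, f1, f2) == expected


class TestReferenceUpdate:
    @staticmethod
    def _state_with_tail(tail):
        state = SearchState(
            algorithm="aru", shape=(5,), alpha=1.0,
            rng=np.random.default_rng(0), current=(0,), current_f=0.0,
        )
        state.reference = (0,)
        state.reference_f = 0.0
        state.tail = list(tail)
        return state

    def test_passed_local_maximum_adopted(self):
        state = self._state_with_tail([((0,), 0.2), ((1,), 0.5)])
        update_reference(state, (2,), 0.4)
        assert state.reference == (1,)
        assert state.reference_f == 0.5

    def test_monotone_run_keeps_reference(self):
        state = self._state_with_tail([((0,), 0.2), ((1,), 0.5)])
        update_reference(state, (2,), 0.7)
        assert state.reference == (0,)

    def test_plateau_requires_strict_inequality(self):
        state = self._state_with_tail([((0,), 0.5), ((1,), 0.5)])
        update_reference(state, (2,), 0.4)
        assert state.reference == (0,)

    def test_too_short_history_is_noop(self):
        state = self._state_with_tail([((0,), 0.2)])
        update_reference(state, (1,), 0.1)
        assert state.reference == (0,)
        assert len(state.tail) == 2


def run_chain(surface, algorithm, steps, seed=0, alpha=1.0, start=None, **kwargs):
    rng = np.random.default_rng(seed)
    oracle = EvaluationOracle(surface, NoiseModel(0.0), strategy="A")
    start = start if start is not None else surface.grid.random_levels(rng)
    f0 = oracle.observe(start)
    state = init_state(
        algorithm, surface.grid.shape, alpha, rng, start, f0, **kwargs
    )
    visits = [start]
    for _ in range(steps):
        visits.append(search_step(state, oracle))
    return state, oracle, visits


class TestStepInvariants:
    @pytest.mark.parametrize(
        "algorithm", ["gur_simultaneous", "gur_sequential", "enhanced", "aru"]
    )
    def test_moves_stay_on_grid_and_change_one_level_per_drug(self, algorithm):
        surface = builtin_surface("f3a")
        _, _, visits = run_chain(surface, algorithm, 400, seed=3)
        shape = surface.grid.shape
        for prev, cur in zip(visits, visits[1:]):
            for k, m in zip(cur, shape):
                assert 0 <= k < m
            deltas = [abs(a - b) for a, b in zip(prev, cur)]
            assert max(deltas) <= 1

    def test_alpha_zero_walk_is_symmetric(self, unimodal11_surface):
        # with alpha = 0 every move is an unbiased coin flip; count interior
        # up-moves over a long 1-D chain
        _, _, visits = run_chain(
            unimodal11_surface, "aru", 10_000, seed=1, alpha=0.0, start=(5,)
        )
        ups = downs = 0
        for prev, cur in zip(visits, visits[1:]):
            if 0 < prev[0] < 10:
                if cur[0] == prev[0] + 1:
                    ups += 1
                elif cur[0] == prev[0] - 1:
                    downs += 1
        n = ups + downs
        assert abs(ups / n - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_aru_climbs_unimodal_surface_quickly(self, unimodal11_surface):
        # informed search should reach the peak within 2*M steps nearly always
        budget = 2 * 11
        hits = 0
        trials = 500
        for seed in range(trials):
            _, _, visits = run_chain(
                unimodal11_surface, "aru", budget, seed=seed, alpha=1.0
            )
            hits += any(v == (7,) for v in visits)
        assert hits / trials >= 0.99


class TestGurFailureModes:
    """The fixed automaton's behavior on badly normalized responses."""

    @staticmethod
    def _flat_surface(level_values):
        from drugcombo import ConcentrationGrid, ResponseSurface

        grid = ConcentrationGrid((np.arange(5, dtype=float),))
        return ResponseSurface.from_table(
            grid, np.array(level_values), name="flat", normalize=False
        )

    def test_low_response_drives_to_reference(self):
        surface = self._flat_surface([0.2, 0.25, 0.2, 0.25, 0.2])
        _, _, visits = run_chain(surface, "gur_sequential", 4000, seed=2, start=(0,))
        occupancy = np.bincount([v[0] for v in visits[500:]], minlength=5)
        assert occupancy.argmax() == 2  # the median reference level

    def test_high_response_drives_to_grid_edges(self):
        surface = self._flat_surface([0.8, 0.85, 0.8, 0.85, 0.8])
        _, _, visits = run_chain(surface, "gur_sequential", 4000, seed=2, start=(2,))
        occupancy = np.bincount([v[0] for v in visits[500:]], minlength=5)
        edge_share = (occupancy[0] + occupancy[4]) / occupancy.sum()
        assert edge_share > 0.5


class TestInitState:
    def test_unknown_algorithm_rejected(self, rng):
        with pytest.raises(ValueError):
            init_state("tabu", (5,), 1.0, rng, (0,), 0.5)

    def test_invalid_edge_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            init_state("aru", (5,), 1.0, rng, (0,), 0.5, edge_mode="wrap")

    def test_invalid_drug_order_rejected(self, rng):
        with pytest.raises(ValueError):
            init_state("aru", (5,), 1.0, rng, (0,), 0.5, drug_order="sorted")

    def test_aru_reference_starts_at_initial_combination(self, rng):
        state = init_state("aru", (5, 5), 1.0, rng, (2, 3), 0.4)
        assert state.reference == (2, 3)
        assert state.reference_f == 0.4
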