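"""Tests for the end-of-generation update: pairwise-comparison imitation,
altruist stubbornness, and Gaussian CCC mutation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pggcoop import (
    INFINITE,
    ImitationRule,
    MutationScope,
    PopulationState,
    SimParams,
    apply_mutations,
    imitation_probability,
    imitation_step,
    init_population,
    mutate_ccc,
    select_partner,
    step_generation,
)
from pggcoop.evolve import _mutate_values


class TestImitationProbability:
    @pytest.mark.parametrize(
        "pi_self, pi_partner, beta, expected",
        [
            (10.0, 10.0, 0.7, 0.5),  # zero difference
            (3.0, 9.0, 0.0, 0.5),  # maximal noise: coin toss
            (8.0, 10.0, 1.0, 1 / (1 + math.exp(-2))),
            (8.0, 10.0, INFINITE, 1.0),  # step-function limit
            (10.0, 8.0, INFINITE, 0.0),
            (10.0, 10.0, INFINITE, 0.0),  # no tie-copying without noise
        ],
    )
    def test_examples(self, pi_self, pi_partner, beta, expected):
        assert imitation_probability(pi_self, pi_partner, beta) == (
            pytest.approx(expected, abs=1e-12)
        )

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            imitation_probability(1.0, 2.0, -0.5)

    @given(
        beta=st.floats(0.01, 5.0),
        d_pair=st.tuples(st.floats(-3, 3), st.floats(-3, 3)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_payoff_difference(self, beta, d_pair):
        lo, hi = min(d_pair), max(d_pair)
        assert imitation_probability(0.0, hi, beta) >= imitation_probability(
            0.0, lo, beta
        ) - 1e-12

    @given(beta=st.floats(0.0, 10.0))
    @settings(max_examples=50, derandomize=True)
    def test_half_at_zero_difference_for_finite_noise(self, beta):
        assert imitation_probability(5.0, 5.0, beta) == 0.5


class TestSelectPartner:
    def test_two_agents(self, rng):
        assert select_partner(0, 2, rng) == 1
        assert select_partner(1, 2, rng) == 0

    def test_never_self(self, rng):
        draws = [select_partner(5, 100, rng) for _ in range(2000)]
        assert 5 not in draws

    def test_uniform_over_others(self, rng):
        n_draws = 10_000
        counts = np.zeros(100)
        for _ in range(n_draws):
            counts[select_partner(5, 100, rng)] += 1
        expected = n_draws / 99
        se = math.sqrt(n_draws * (1 / 99) * (98 / 99))
        assert counts[5] == 0
        others = np.delete(counts, 5)
        assert (np.abs(others - expected) < 5 * se).all()

    def test_too_few_agents(self, rng):
        with pytest.raises(ValueError):
            select_partner(0, 1, rng)


def _make_state(ccc, is_altruist, payoffs, n_coop=0):
    n = len(ccc)
    return PopulationState(
        is_altruist=np.asarray(is_altruist, dtype=bool),
        ccc=np.asarray(ccc, dtype=np.int64),
        contributions=np.zeros(n),
        payoffs=np.asarray(payoffs, dtype=float),
        n_cooperators=n_coop,
    )


class TestImitationStep:
    def test_equal_payoffs_gated_changes_nothing(self, rng):
        params = SimParams(n_agents=10, imitation_rule=ImitationRule.GATED)
        state = _make_state(
            np.arange(10), np.zeros(10), np.full(10, 10.0)
        )
        out = imitation_step(state, params, rng)
        assert (out.new_ccc == state.ccc).all()
        assert not out.imitated_flags.any()

    def test_noise_free_role_model_always_copied(self, rng):
        # one agent with strictly maximal payoff: every agent drawing it
        # adopts its strategy with certainty
        params = SimParams(n_agents=8, noise=INFINITE)
        pay = np.full(8, 10.0)
        pay[3] = 11.0
        state = _make_state(np.arange(8), np.zeros(8), pay)
        found_adoption = False
        for _ in range(50):
            out = imitation_step(state, params, rng)
            adopted = out.new_ccc != state.ccc
            assert (out.new_ccc[adopted] == 3).all()
            found_adoption |= adopted.any()
        assert found_adoption

    def test_fully_stubborn_altruists_never_change(self, rng):
        params = SimParams(n_agents=10, stubbornness=1.0, noise=2.0)
        alt = np.zeros(10, dtype=bool)
        alt[:4] = True
        pay = np.linspace(9, 11, 10)
        state = _make_state([0, 0, 0, 0, 5, 6, 7, 8, 9, 10], alt, pay)
        for _ in range(30):
            out = imitation_step(state, params, rng)
            assert (out.new_ccc[:4] == 0).all()

    def test_non_stubborn_altruists_can_imitate(self, rng):
        params = SimParams(n_agents=6, stubbornness=0.0, noise=INFINITE)
        alt = np.array([True, False, False, False, False, False])
        pay = np.array([9.0, 11.0, 11.0, 11.0, 11.0, 11.0])
        state = _make_state([0, 4, 4, 4, 4, 4], alt, pay)
        out = imitation_step(state, params, rng)
        assert out.new_ccc[0] == 4  # poorest agent, partner always richer

    def test_synchronous_update_reads_pre_update_values(self, rng):
        # with noise-free imitation and payoffs increasing with index, every
        # adopted value is one of the ORIGINAL ccc values, not a cascade
        params = SimParams(n_agents=20, noise=INFINITE)
        ccc = np.arange(20)
        pay = np.linspace(9, 11, 20)
        state = _make_state(ccc, np.zeros(20), pay)
        out = imitation_step(state, params, rng)
        assert set(out.new_ccc).issubset(set(ccc))


class TestMutation:
    @pytest.mark.parametrize(
        "ccc, raw, expected",
        [
            (98, 15.0, 100),  # clamped to N from above
            (2, -7.4, 0),  # clamped to 0 from below
            (50, 0.0, 50),  # identity increment
            (50, 0.4, 50),  # rounds to nearest integer
            (50, 60.0, 100),  # raw draw clipped to +bound first
            (50, -60.0, 0),
        ],
    )
    def test_increment_arithmetic(self, ccc, raw, expected):
        params = SimParams()
        out = _mutate_values(
            np.array([ccc]), np.array([raw]), params
        )
        assert out[0] == expected

    def test_mutate_ccc_stays_in_range(self, rng):
        params = SimParams()
        for ccc in (0, 1, 50, 99, 100):
            for _ in range(200):
                assert 0 <= mutate_ccc(ccc, params, rng) <= 100

    def test_out_of_range_ccc_rejected(self, rng):
        with pytest.raises(ValueError):
            mutate_ccc(101, SimParams(), rng)

    @given(
        ccc=st.integers(0, 100),
        raw=st.floats(-1000, 1000, allow_nan=False),
    )
    @settings(max_examples=300, derandomize=True)
    def test_range_preserved_for_any_draw(self, ccc, raw):
        out = _mutate_values(np.array([ccc]), np.array([raw]), SimParams())
        assert 0 <= out[0] <= 100

    def test_zero_rate_leaves_outcome_unchanged(self, rng):
        params = SimParams(n_agents=10, mutation_rate=0.0)
        state = _make_state(np.arange(10), np.zeros(10), np.full(10, 10.0))
        out = imitation_step(state, params, rng)
        before = out.new_ccc.copy()
        out = apply_mutations(out, state.is_altruist, params, rng)
        assert (out.new_ccc == before).all()
        assert not out.mutated_flags.any()

    def test_altruists_never_mutated(self, rng):
        params = SimParams(n_agents=10, mutation_rate=1.0)
        alt = np.zeros(10, dtype=bool)
        alt[:5] = True
        state = _make_state(np.zeros(10), alt, np.full(10, 10.0))
        out = imitation_step(state, params, rng)
        out = apply_mutations(out, state.is_altruist, params, rng)
        assert not out.mutated_flags[:5].any()
        assert out.mutated_flags[5:].all()

    def test_imitators_only_scope(self, rng):
        params = SimParams(
            n_agents=10,
            mutation_rate=1.0,
            mutation_scope=MutationScope.IMITATORS_ONLY,
        )
        state = _make_state(np.arange(10), np.zeros(10), np.full(10, 10.0))
        out = imitation_step(state, params, rng)  # equal payoffs: coin flips
        out = apply_mutations(out, state.is_altruist, params, rng)
        assert (out.mutated_flags <= out.imitated_flags).all()

    def test_mutation_count_matches_rate(self):
        # 5% of 100 conditionals: mean 5 mutants per generation
        params = SimParams(n_agents=100, altruist_fraction=0.0)
        rng = np.random.default_rng(0)
        state = init_population(params, rng)
        total = 0
        reps = 2000
        for _ in range(reps):
            out = imitation_step(state, params, rng)
            out = apply_mutations(out, state.is_altruist, params, rng)
            total += out.mutated_flags.sum()
        mean = total / reps
        se = math.sqrt(100 * 0.05 * 0.95 / reps)
        assert abs(mean - 5.0) < 4 * se


class TestStepGeneration:
    def test_deterministic_given_seed(self, small_params):
        r1, r2 = np.random.default_rng(99), np.random.default_rng(99)
        s1 = init_population(small_params, r1)
        s2 = init_population(small_params, r2)
        for _ in range(10):
            s1, _ = step_generation(s1, small_params, r1)
            s2, _ = step_generation(s2, small_params, r2)
        assert (s1.ccc == s2.ccc).all()
        assert (s1.contributions == s2.contributions).all()
        assert s1.n_cooperators == s2.n_cooperators

    def test_all_altruists_always_cooperate(self, rng):
        params = SimParams(altruist_fraction=1.0, generations=5)
        state = init_population(params, rng)
        for _ in range(5):
            state, rec = step_generation(state, params, rng)
            assert rec.coop_level == 1.0

    def test_records_bounded_cooperation(self, small_params, rng):
        state = init_population(small_params, rng)
        for _ in range(20):
            state, rec = step_generation(state, small_params, rng)
            assert 0.0 <= rec.coop_level <= 1.0
            assert rec.coop_level == state.n_cooperators / 100

    def test_payoff_conservation_every_round(self, small_params, rng):
        state = init_population(small_params, rng)
        for _ in range(30):
            state, _ = step_generation(state, small_params, rng)
            expected = 100 * 10.0 + 0.5 * state.contributions.sum()
            assert state.payoffs.sum() == pytest.approx(expected, abs=1e-9)

    def test_ccc_stays_in_range(self, small_params, rng):
        state = init_population(small_params, rng)
        for _ in range(50):
            state, _ = step_generation(state, small_params, rng)
            assert state.ccc.min() >= 0
            assert state.ccc.max() <= 100
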