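"""End-of-generation strategy update.

After each PGG round every agent is matched with a random partner and may
adopt the partner's CCC through a noisy pairwise-comparison (Fermi) process
driven by the payoff difference.  Altruists skip this process with
probability ``w`` (their "stubbornness").  Finally a small fraction of
conditional cooperators mutate: a truncated Gaussian increment is added to
their CCC and the result is clamped back into {0, ..., N}.

The update is synchronous: all adoptions read the pre-update CCC values.
The per-generation random-draw order is fixed (decisions, pairings,
stubbornness checks, imitation coin flips, mutation selection, mutation
draws) and every draw is a full length-N vector, so results are
bit-reproducible regardless of which agents end up eligible for each stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .core import (
    ImitationRule,
    MutationScope,
    PopulationState,
    SimParams,
    compute_payoffs,
    decision_probability,
    draw_decisions,
)

__all__ = [
    "UpdateOutcome",
    "GenerationRecord",
    "imitation_probability",
    "select_partner",
    "imitation_step",
    "mutate_ccc",
    "apply_mutations",
    "step_generation",
]


@dataclass
class UpdateOutcome:
    """Result of one generation's imitation + mutation pass."""

    new_ccc: np.ndarray  # int, length N
    imitated_flags: np.ndarray  # bool, length N
    mutated_flags: np.ndarray  # bool, length N


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation observables recorded along a trajectory."""

    generation: int
    coop_level: float
    n_imitated: int
    n_mutated: int


def imitation_probability(payoff_self, payoff_partner, noise: float):
    """Probability of adopting the partner's strategy under the
    pairwise-comparison rule: logistic in (pi_partner - pi_self) with slope
    beta.  beta = 0 is a coin toss; beta = INFINITE is the step function:
    adopt iff the partner earned strictly more, never on ties (with perfect
    payoff information, equally-fit agents each keep their own strategy —
    copying on ties is an artifact of noise and vanishes in this limit).

    Accepts scalars or arrays.
    """
    if math.isnan(noise) or noise < 0:
        raise ValueError(f"noise must be >= 0 or infinite, got {noise}")
    diff = np.asarray(payoff_partner, dtype=float) - np.asarray(
        payoff_self, dtype=float
    )
    if math.isinf(noise):
        q = np.where(diff > 0, 1.0, 0.0)
    else:
        q = expit(diff * noise)  # noise == 0 gives 0.5 everywhere
    if np.isscalar(payoff_self) and np.isscalar(payoff_partner):
        return float(q)
    return q


def select_partner(index: int, n_agents: int, rng: np.random.Generator) -> int:
    """Uniform random partner for ``index`` among the other N - 1 agents."""
    if n_agents < 2:
        raise ValueError("partner selection requires at least 2 agents")
    j = int(rng.integers(0, n_agents - 1))
    return j + 1 if j >= index else j


def _select_partners(n_agents: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized self-excluding partner draw, one per agent."""
    idx = np.arange(n_agents)
    j = rng.integers(0, n_agents - 1, size=n_agents)
    return j + (j >= idx)


def imitation_step(
    state: PopulationState, params: SimParams, rng: np.random.Generator
) -> UpdateOutcome:
    """Synchronous pairwise-comparison update of the whole population.

    Every agent draws a partner; altruists take part only when their
    stubbornness check fails (probability 1 - w).  Under the GATED rule an
    agent can switch only to a strictly better-earning partner; under FERMI
    the logistic probability applies regardless of sign.  All adoptions copy
    pre-update CCC values.
    """
    n = state.n_agents
    partners = _select_partners(n, rng)
    stubborn_draws = rng.random(n)
    coin_flips = rng.random(n)

    participates = np.where(
        state.is_altruist, stubborn_draws >= params.stubbornness, True
    )
    q = imitation_probability(
        state.payoffs, state.payoffs[partners], params.noise
    )
    adopt = participates & (coin_flips < q)
    if params.imitation_rule is ImitationRule.GATED:
        adopt &= state.payoffs[partners] > state.payoffs

    new_ccc = np.where(adopt, state.ccc[partners], state.ccc)
    return UpdateOutcome(
        new_ccc=new_ccc.astype(np.int64),
        imitated_flags=adopt,
        mutated_flags=np.zeros(n, dtype=bool),
    )


def _mutate_values(
    ccc: np.ndarray, raw_draws: np.ndarray, params: SimParams
) -> np.ndarray:
    """Apply raw Gaussian increments: clip to +/-bound, add, round to the
    nearest integer, clamp into {0, ..., N}."""
    inc = np.clip(raw_draws, -params.mutation_bound, params.mutation_bound)
    mutated = np.rint(np.asarray(ccc, dtype=float) + inc)
    return np.clip(mutated, 0, params.n_agents).astype(np.int64)


def mutate_ccc(
    ccc: int, params: SimParams, rng: np.random.Generator
) -> int:
    """Mutate a single CCC value with one truncated Gaussian increment."""
    if not (0 <= ccc <= params.n_agents):
        raise ValueError(f"ccc must lie in [0, {params.n_agents}], got {ccc}")
    raw = rng.normal(0.0, params.mutation_sd)
    return int(_mutate_values(np.array([ccc]), np.array([raw]), params)[0])


def apply_mutations(
    outcome: UpdateOutcome,
    is_altruist: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> UpdateOutcome:
    """Mutate eligible conditional cooperators in place.

    Eligibility follows ``params.mutation_scope``; altruists are never
    mutated.  A conditional whose CCC reaches 0 stays a conditional.
    """
    n = outcome.new_ccc.shape[0]
    selection_draws = rng.random(n)
    raw_draws = rng.normal(0.0, params.mutation_sd, size=n)

    eligible = ~np.asarray(is_altruist)
    if params.mutation_scope is MutationScope.IMITATORS_ONLY:
        eligible &= outcome.imitated_flags
    mutate = eligible & (selection_draws < params.mutation_rate)

    mutated_vals = _mutate_values(outcome.new_ccc, raw_draws, params)
    outcome.new_ccc = np.where(mutate, mutated_vals, outcome.new_ccc)
    outcome.mutated_flags = mutate
    return outcome


def step_generation(
    state: PopulationState, params: SimParams, rng: np.random.Generator
) -> tuple[PopulationState, GenerationRecord]:
    """Advance the population by one generation.

    Order: decisions conditioned on the previous round's N_C, payoffs,
    cooperation-level record, imitation on this round's payoffs, mutation,
    then roll N_C forward.
    """
    contrib = draw_decisions(state, params, rng)
    payoffs = compute_payoffs(contrib, params)
    n_coop = int(np.count_nonzero(contrib == params.contribution_cost))

    played = PopulationState(
        is_altruist=state.is_altruist,
        ccc=state.ccc,
        contributions=contrib,
        payoffs=payoffs,
        n_cooperators=n_coop,
        generation=state.generation + 1,
    )
    outcome = imitation_step(played, params, rng)
    outcome = apply_mutations(outcome, played.is_altruist, params, rng)
    played.ccc = outcome.new_ccc
    record = GenerationRecord(
        generation=played.generation,
        coop_level=n_coop / params.n_agents,
        n_imitated=int(outcome.imitated_flags.sum()),
        n_mutated=int(outcome.mutated_flags.sum()),
    )
    return played, record


def update_population(
    state: PopulationState, params: SimParams, rng: np.random.Generator
) -> PopulationState:
    """Apply only the end-of-generation update (imitation + mutation) to a
    state whose round has already been played — used for generation 1,
    whose contributions are fixed by convention rather than drawn."""
    outcome = imitation_step(state, params, rng)
    outcome = apply_mutations(outcome, state.is_altruist, params, rng)
    new_state = state.copy()
    new_state.ccc = outcome.new_ccc
    return new_state
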