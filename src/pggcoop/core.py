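"""Core machinery of the repeated public goods game (PGG).

A population of ``N`` agents plays one PGG round per generation.  Each agent
carries a *conditional cooperative criterion* (CCC): the minimum number of
previous-round contributors it requires before it will (probabilistically)
contribute itself.  Altruists are agents born with CCC = 0 that, in addition,
largely opt out of the imitation process (see :mod:`pggcoop.evolve`).

This module holds the parameter container, the population state, the noisy
threshold decision rule, the payoff rule, and population initialisation.
All randomness flows through an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.special import expit

__all__ = [
    "INFINITE",
    "UNSET",
    "AgentType",
    "ImitationRule",
    "MutationScope",
    "ZeroCCCRule",
    "SimParams",
    "Agent",
    "PopulationState",
    "decision_probability",
    "draw_decisions",
    "compute_payoffs",
    "init_population",
]

#: Distinguished noise value for the noise-free (perfect information) limit.
#: Decisions and imitation become deterministic step functions of their
#: argument; the logistic is never evaluated at this value.
INFINITE = math.inf

#: Sentinel for "no exogenous first-generation cooperation level".
UNSET = None


class AgentType(enum.Enum):
    ALTRUIST = "altruist"
    CONDITIONAL = "conditional"


class ImitationRule(enum.Enum):
    """How the pairwise-comparison update treats the payoff comparison.

    GATED: an agent considers switching only when the partner's payoff is
    strictly higher (the partner is a "role model"), then switches with the
    logistic probability.  FERMI: the plain pairwise-comparison process where
    the logistic probability applies regardless of the sign of the payoff
    difference.
    """

    GATED = "gated"
    FERMI = "fermi"


class MutationScope(enum.Enum):
    """Which conditional cooperators are eligible for CCC mutation each
    generation: all of them, or only those that imitated this generation."""

    ALL_CONDITIONALS = "all_conditionals"
    IMITATORS_ONLY = "imitators_only"


class ZeroCCCRule(enum.Enum):
    """Who contributes unconditionally (probability 1) regardless of noise.

    ALTRUISTS_ONLY (default): only altruist-type agents are unconditional;
    a conditional cooperator whose CCC reached 0 still follows the logistic
    rule, so at beta = 0 it tosses a coin like every other conditional.
    This is what makes the maximal-noise cooperation level come out at
    alpha + (1 - alpha)/2 exactly.  ALL_ZERO_CCC: any agent with CCC = 0
    contributes with probability 1, the literal threshold-rule reading.
    The two differ only at beta = 0 or when N_C * beta is tiny.
    """

    ALTRUISTS_ONLY = "altruists_only"
    ALL_ZERO_CCC = "all_zero_ccc"


def _validate_noise(noise: float) -> float:
    noise = float(noise)
    if math.isnan(noise) or noise < 0:
        raise ValueError(f"noise must be >= 0 or infinite, got {noise}")
    return noise


@dataclass(frozen=True)
class SimParams:
    """Complete parameterization of one experimental condition.

    Parameters
    ----------
    n_agents : int
        Population size N.
    endowment : float
        Per-round endowment e given to every agent (payoff units).
    contribution_cost : float
        Cost u of contributing; contributions are 0 or u, with 0 < u <= e.
    enhancement : float
        Enhancement factor h > 1 applied to the common pool.
    altruist_fraction : float
        Fraction alpha of agents created as altruists (CCC = 0, stubborn).
    noise : float
        Inverse noise intensity beta >= 0; ``INFINITE`` selects the
        perfect-information limit.  beta = 0 is pure coin tossing.
    stubbornness : float
        Probability w that an altruist skips the imitation process in a
        given generation.
    mutation_rate : float
        Per-generation probability that a conditional cooperator's CCC is
        perturbed.
    mutation_sd : float
        Standard deviation of the Gaussian CCC perturbation.
    mutation_bound : float
        Absolute cap applied to the raw Gaussian draw before rounding.
    generations : int
        Number of PGG rounds (generations) per replicate.
    replicates : int
        Number of independent replicate runs.
    imitation_rule : ImitationRule
        GATED (default) or FERMI; see :class:`ImitationRule`.
    mutation_scope : MutationScope
        ALL_CONDITIONALS (default) or IMITATORS_ONLY.
    initial_coop_fraction : float or None
        Exogenous first-generation cooperation level; only valid in
        altruist-free runs (alpha = 0).
    base_seed : int
        Seed of replicate 0; replicate r uses base_seed + r.
    """

    n_agents: int = 100
    endowment: float = 10.0
    contribution_cost: float = 0.5
    enhancement: float = 1.5
    altruist_fraction: float = 0.0
    noise: float = 0.5
    stubbornness: float = 1.0
    mutation_rate: float = 0.05
    mutation_sd: float = 5.0
    mutation_bound: float = 50.0
    generations: int = 20_000
    replicates: int = 30
    imitation_rule: ImitationRule = ImitationRule.FERMI
    mutation_scope: MutationScope = MutationScope.ALL_CONDITIONALS
    zero_ccc_rule: ZeroCCCRule = ZeroCCCRule.ALTRUISTS_ONLY
    initial_coop_fraction: float | None = UNSET
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be a positive integer")
        if self.endowment < 0:
            raise ValueError("endowment must be non-negative")
        if not (0 < self.contribution_cost <= self.endowment):
            raise ValueError(
                "contribution_cost must lie in (0, endowment]: "
                f"got u={self.contribution_cost}, e={self.endowment}"
            )
        if self.enhancement <= 1:
            raise ValueError("enhancement must exceed 1")
        for name in ("altruist_fraction", "stubbornness", "mutation_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        _validate_noise(self.noise)
        if self.mutation_sd <= 0 or self.mutation_bound <= 0:
            raise ValueError("mutation_sd and mutation_bound must be positive")
        if self.generations < 1:
            raise ValueError("generations must be a positive integer")
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")
        if self.initial_coop_fraction is not UNSET:
            if not (0 <= self.initial_coop_fraction <= 1):
                raise ValueError("initial_coop_fraction must lie in [0, 1]")
            if self.altruist_fraction > 0:
                raise ValueError(
                    "initial_coop_fraction is only meaningful without "
                    "altruists; set altruist_fraction=0 or drop it"
                )
        if not isinstance(self.imitation_rule, ImitationRule):
            object.__setattr__(
                self, "imitation_rule", ImitationRule(self.imitation_rule)
            )
        if not isinstance(self.mutation_scope, MutationScope):
            object.__setattr__(
                self, "mutation_scope", MutationScope(self.mutation_scope)
            )
        if not isinstance(self.zero_ccc_rule, ZeroCCCRule):
            object.__setattr__(
                self, "zero_ccc_rule", ZeroCCCRule(self.zero_ccc_rule)
            )

    @property
    def n_altruists(self) -> int:
        return int(round(self.altruist_fraction * self.n_agents))

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Agent:
    """Scalar view of one agent: its immutable type and current CCC."""

    agent_type: AgentType
    ccc: int


@dataclass
class PopulationState:
    """State of the population after the most recent PGG round.

    Arrays are aligned by agent index.  ``contributions`` holds values in
    {0, u}; ``n_cooperators`` is the contributor head-count N_C that the
    next round's decisions condition on.
    """

    is_altruist: np.ndarray  # bool, length N
    ccc: np.ndarray  # int, length N, values in {0,...,N}
    contributions: np.ndarray  # float, length N, values in {0, u}
    payoffs: np.ndarray  # float, length N
    n_cooperators: int
    generation: int = 1

    @property
    def n_agents(self) -> int:
        return self.ccc.shape[0]

    @property
    def agents(self) -> Iterator[Agent]:
        for alt, c in zip(self.is_altruist, self.ccc):
            yield Agent(
                AgentType.ALTRUIST if alt else AgentType.CONDITIONAL, int(c)
            )

    def cooperation_level(self) -> float:
        return self.n_cooperators / self.n_agents

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.is_altruist.copy(),
            self.ccc.copy(),
            self.contributions.copy(),
            self.payoffs.copy(),
            self.n_cooperators,
            self.generation,
        )


def decision_probability(ccc, n_coop_prev, noise: float, *,
                         unconditional_zero: bool = True):
    """Probability that an agent with threshold ``ccc`` contributes, given
    ``n_coop_prev`` contributors in the previous round.

    The rule is logistic in (N_C - CCC) with slope ``noise`` (beta):
    beta = 0 or N_C = CCC is a coin toss; beta = INFINITE is the
    deterministic threshold rule (contribute iff N_C > CCC).  With
    ``unconditional_zero`` (the default) CCC = 0 contributes with
    probability 1 regardless of noise; pass False to apply the logistic to
    CCC = 0 as well (the branch population simulations use for conditional
    cooperators, see :class:`ZeroCCCRule`).

    Accepts scalars or arrays for ``ccc`` / ``n_coop_prev``.
    """
    noise = _validate_noise(noise)
    ccc_arr = np.asarray(ccc)
    nc_arr = np.asarray(n_coop_prev)
    if np.any(ccc_arr < 0) or np.any(nc_arr < 0):
        raise ValueError("ccc and n_coop_prev must be non-negative")
    diff = nc_arr.astype(float) - ccc_arr.astype(float)
    if math.isinf(noise):
        p = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    elif noise == 0.0:
        p = np.full(np.broadcast(ccc_arr, nc_arr).shape, 0.5)
    else:
        p = expit(diff * noise)
    if unconditional_zero:
        p = np.where(ccc_arr == 0, 1.0, p)
    if np.isscalar(ccc) and np.isscalar(n_coop_prev):
        return float(p)
    return p


def draw_decisions(
    state: PopulationState, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw one round of contribution decisions.

    Each agent contributes ``u`` independently with the probability of
    :func:`decision_probability` at the previous round's N_C.  Altruists
    always contribute; whether a conditional cooperator with CCC = 0 also
    does, or coin-tosses at beta = 0 like every other conditional, follows
    ``params.zero_ccc_rule``.
    """
    p = decision_probability(
        state.ccc,
        state.n_cooperators,
        params.noise,
        unconditional_zero=(
            params.zero_ccc_rule is ZeroCCCRule.ALL_ZERO_CCC
        ),
    )
    p = np.where(state.is_altruist & (state.ccc == 0), 1.0, p)
    coop = rng.random(state.n_agents) < p
    return np.where(coop, params.contribution_cost, 0.0)


def compute_payoffs(contributions: np.ndarray, params: SimParams) -> np.ndarray:
    """Per-agent PGG payoff: pi_i = (e - c_i) + (h/N) * sum_j c_j.

    The pool of contributions is scaled by the enhancement factor h and
    shared equally, so defectors earn the public share without the cost.
    """
    c = np.asarray(contributions, dtype=float)
    valid = (c == 0.0) | (c == params.contribution_cost)
    if not valid.all():
        bad = c[~valid][0]
        raise ValueError(
            f"contributions must be 0 or u={params.contribution_cost}, got {bad}"
        )
    pool_share = params.enhancement / params.n_agents * c.sum()
    return (params.endowment - c) + pool_share


def init_population(
    params: SimParams, rng: np.random.Generator
) -> PopulationState:
    """Create the generation-1 population and play its (conventional) round.

    round(alpha * N) altruists get CCC = 0; the remaining conditionals draw
    CCC uniformly from the N + 1 integers {0, ..., N}.  Generation 1 has no
    previous round to condition on, so its contributions follow a
    convention: altruists contribute, conditionals do not — unless an
    exogenous ``initial_coop_fraction`` (altruist-free runs only) selects
    round(f * N) conditionals as first-round contributors.
    """
    n = params.n_agents
    n_alt = params.n_altruists
    is_altruist = np.zeros(n, dtype=bool)
    is_altruist[:n_alt] = True
    ccc = np.empty(n, dtype=np.int64)
    ccc[:n_alt] = 0
    ccc[n_alt:] = rng.integers(0, n + 1, size=n - n_alt)

    contrib = np.zeros(n, dtype=float)
    contrib[:n_alt] = params.contribution_cost
    if params.initial_coop_fraction is not UNSET:
        n_seeded = int(round(params.initial_coop_fraction * n))
        seeded = rng.choice(n, size=n_seeded, replace=False)
        contrib[seeded] = params.contribution_cost

    payoffs = compute_payoffs(contrib, params)
    n_coop = int(np.count_nonzero(contrib == params.contribution_cost))
    return PopulationState(
        is_altruist=is_altruist,
        ccc=ccc,
        contributions=contrib,
        payoffs=payoffs,
        n_cooperators=n_coop,
        generation=1,
    )
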