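# Methods

## Model

One generation is one round of an N-player public goods game followed by
one synchronous strategy-update pass.

**Decisions.** Agent `i` contributes `u` with probability
`p_i = logistic((N_C − CCC_i) β)`, where `N_C` is the contributor count of
the previous round. `β = 0` and `N_C = CCC_i` both give a coin toss;
`β = ∞` is the strict threshold rule (contribute iff `N_C > CCC_i`, coin
toss at equality). Altruists whose `CCC` is 0 contribute with probability
1. A conditional cooperator whose `CCC` reached 0 (by imitation or
mutation) follows the logistic like every other conditional — so at
`β = 0` it coin-tosses. This asymmetry between the two agent types is
deliberate: it is what makes the maximal-noise cooperation level come out
at exactly `α + (1 − α)/2`, the value the `β = 0` anchor demands
(`SimParams.zero_ccc_rule = ALL_ZERO_CCC` switches to the literal
threshold-rule semantics in which any `CCC = 0` agent contributes with
probability 1; the two differ only at `β = 0` or when `N_C β` is tiny).

**Payoffs.** `π_i = (e − c_i) + (h/N) Σ_j c_j`. The identity
`Σ π_i = N e + (h − 1) Σ c_i` holds to 1e−9 and is asserted along real
trajectories in the tests.

**Imitation.** Each agent draws a uniform partner (self excluded; several
agents may draw the same partner) and adopts the partner's pre-update
`CCC` with probability `q = logistic((π_j − π_i) β)` — the
pairwise-comparison (Fermi) rule. The update is synchronous: all adoptions
read pre-update values. Altruists participate only when their
stubbornness check fails (probability `1 − w`); an altruist that imitated
keeps the adopted `CCC` (no automatic reset) but retains its type, so the
stubbornness check and the mutation exemption keep applying and its
decisions now follow its adopted threshold.

Two rule variants are provided. The default, `FERMI`, applies `q`
regardless of the sign of the payoff difference: the noise that garbles
payoff perception acts on the whole comparison, so an agent sometimes
copies a worse-off partner, and at `β = 0` the entire decision degenerates
to a coin toss. The alternative, `GATED`, restricts switching to strictly
better-earning partners (`π_j > π_i`) and applies `q` inside that gate.
The choice matters enormously: because defectors out-earn contributors by
`u` in every round, `GATED` makes strategy flow one-directional toward
free riding and cooperation collapses to the altruist fraction at every
`β > 0` — the acceptance suite's interior-cooperation checks cannot be
satisfied by it, which is why `FERMI` is the default.

In the `β = ∞` limit `q` is the step function, and *no* imitation happens
on exact payoff ties: with perfect payoff information an equally-fit
partner offers no reason to switch; tie-copying is an artifact of noise
and must vanish in this limit. (With 0.5-probability tie-copying instead,
about a third of noise-free replicates lock into full cooperation after
the early decision cascade, because once everyone contributes, payoffs are
identical, ties are everywhere, and strategies keep mixing toward the
altruists' `CCC = 0`; with no tie-copying every noise-free replicate
collapses to the altruist fraction, as the limit analysis requires.)

**Mutation.** Each generation, each conditional cooperator mutates with
probability `mutation_rate` (default 0.05): a `Normal(0, 5)` increment is
clipped to ±50, added to its `CCC`, rounded to the nearest integer, and
clamped into `{0, …, N}`. Clipping (not resampling) at the bound and
integer rounding keep the declared integer domain; altruists never mutate;
a conditional mutated to `CCC = 0` stays a conditional.
`mutation_scope = IMITATORS_ONLY` restricts eligibility to agents that
imitated in the same generation (a "miscopy" reading); the default mutates
all conditionals.

**Generation 1.** There is no previous round to condition on, so the first
round is fixed by convention: altruists contribute, conditionals do not —
unless an explicit `initial_coop_fraction` (altruist-free runs only)
selects a random set of first-round contributors. The first generation's
payoffs feed a normal update pass, so generation 1 is a full generation.

## Parameters

| name | symbol | default | meaning |
|---|---|---|---|
| `n_agents` | N | 100 | population size |
| `endowment` | e | 10 | per-round endowment (payoff units) |
| `contribution_cost` | u | 0.5 | cost of contributing, 0 < u ≤ e |
| `enhancement` | h | 1.5 | common-pool multiplier, h > 1 |
| `altruist_fraction` | α | 0 | fraction created as altruists |
| `noise` | β | 0.5 | inverse noise; `inf` = perfect information |
| `stubbornness` | w | 1 | P(altruist skips imitation) per generation |
| `mutation_rate` | — | 0.05 | per-conditional mutation probability |
| `mutation_sd` / `mutation_bound` | — | 5 / 50 | Gaussian step and clip |
| `generations` | G | 20,000 | rounds per replicate |
| `replicates` | R | 30 | independent runs, seeds base_seed + r |

## Determinism and problem sizes

Every replicate is a pure function of `(params, seed)`: one
`numpy.random.Generator` per replicate, with a fixed per-generation draw
order (decision draws, partner draws, stubbornness draws, imitation coin
flips, mutation selection, mutation increments — always full length-N
vectors, so the stream layout never depends on which agents are eligible).
Replicates use seeds `base_seed + r` and can run in any order.

The default full profile is 20,000 generations × 30 replicates with a
final-5,000-generation window for asymptotic statistics. The test suite
and the acceptance script use a scaled profile — 5,000 generations × 10
replicates, final-1,000 window (2,000 generations for the noise-limit
checks, which converge within a few hundred) — chosen because every
regime the suite measures is stationary well before those horizons; the
scaled numbers agree with full-profile runs to well within
between-replicate noise.

## Behaviour and regimes

The simulator's computed regimes (all reproduced by the tests and the
acceptance script) are:

- `β = 0`: cooperation sits at `α + (1 − α)/2` exactly, independent of the
  strategy distribution.
- `β = ∞`, `w = 1`: cooperation collapses to `α`; the final strategy
  distribution puts the altruists at `CCC = 0` and the majority of
  conditionals above `CCC = 50`. The measured level exceeds `α` by a few
  hundredths of a percentage point — mutation keeps a tiny standing stock
  of below-threshold conditionals that cooperate for a generation before
  being converted — which the analytic formula neglects.
- Moderate noise (β ≲ 1) with altruists present: the decision feedback
  (more contributors → more thresholds met → more contributors) drives
  cooperation toward saturation within tens of generations; near-neutral
  noisy imitation plus the altruist anchor then concentrates most
  strategies at `CCC = 0`. Persistent interior free-rider pools do not
  survive under either imitation rule at these noise levels.
- Without altruists, cooperation declines from any initial level — the
  sign test over 30 replicates at generation 20 is significant for every
  initial level between 20% and 90%.

## Known limitations

- Well-mixed population only: no spatial or network structure, no group
  sampling within the PGG.
- Binary contributions at a fixed cost; homogeneous endowments.
- The conditionality itself does not evolve — thresholds change only by
  copying and mutation, and types are immutable.
- Between the saturating moderate-noise regime and the collapsing
  noise-free limit (β roughly 1.5–4 at the default payoffs) the dynamics
  are bistable: replicates split between near-full cooperation and
  collapse, so summary means there carry large between-replicate variance
  and depend on horizon length.
- The synthetic populations emulate the stated distributional assumptions
  (uniform initial thresholds, Gaussian mutation); they do not emulate
  empirically measured human threshold distributions, so quantitative
  levels should be read as model outputs, not behavioural predictions.
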