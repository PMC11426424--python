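# Methods

This note documents the model implemented by `refinebandit`, the parameter
choices that matter, the numerical conventions, and what the shipped
experiments do and do not demonstrate.

## The world

The environment is a restless multi-armed bandit with `n_behaviors = 100`
arms per deme. Basic payoffs are independent draws of `round(2·X²)` with
`X ~ Exponential(1)`: integer values, mostly in 0–50, with a long right
tail (mean 4). Each round every payoff is independently replaced by a
fresh draw with probability `p_c`; `p_c` therefore also equals the expected
per-round fraction of arms that change. Under spatial structure there are
three demes with independently drawn and independently changing payoff
tables over a shared behavior index space.

Rounding of basic payoffs is half-away-from-zero. The paper-facing
quantity is simply "rounded"; the convention is fixed so results are
bit-stable across platforms.

## Refinement

Under the cumulative extension an agent may REFINE a known behavior,
incrementing a private per-agent, per-behavior refinement level `r`
(capped at `r_max`). The payoff to a behavior is its current basic payoff
plus an increment

```
i(r) = (0.05 / (1 − 0.95^r_max)) · Σ_{j=1..r} 0.95^(r−j) · p_max
     = p_max · (1 − 0.95^r) / (1 − 0.95^r_max)
```

a diminishing-returns geometric form with `i(0) = 0` and
`i(r_max) = p_max`. The increment is unaffected by basic-payoff redraws:
refinement is knowledge held by the agent, not a property of the
environment, and the environment stores no refinement state.

**Choice of `p_max` (default 125).** The functional form fixes everything
except the ceiling `p_max`, which is a free configuration parameter. The
default is calibrated against the intended geometry of the model: with
`r_max = 100`, the increment should first exceed the highest basic payoff
of a typical freshly drawn 100-behavior environment after roughly 10
refinements, and refinement levels above 8 should typically yield payoffs
beyond the best basic payoff. The median maximum of 100 basic-payoff draws
is ≈ 50, and `p_max = 125` places the first-overtaking level at a median
of 10 (`p_max = 100`, for comparison, would put it at 14). The calibration
is recomputed, not assumed, by `scripts/acceptance.py`.

Refinement levels are hidden from strategies on both sides: the refiner
learns only the new exact total payoff, and an observer copies a behavior
*at the model's level* without knowing what that level is. Copying a
behavior already known overwrites the observer's record with the
demonstrated level and noisy payoff — including when the demonstrated
level is lower (the engine treats the demonstration as the authoritative
template; nothing in the model lets an observer merge two variants).

## Moves and round resolution

Rounds are resolved in two phases: all strategies are queried against
their pre-round views and EXPLOIT/INNOVATE/REFINE are applied; then
OBSERVE moves are processed with this round's same-deme, non-forfeited
exploiters as the model pool. Query order therefore never affects model
availability.

Observation samples up to `n_observe` distinct models without replacement
(the observer is never in its own pool — it is not exploiting). Each
copying event independently fails with probability `p_copyFail` and is
consumed either way: with `n_observe = 5` and two failures, exactly three
models are learned from. Successful copies record a
`Poisson(true received payoff)` estimate, so larger payoffs carry larger
absolute errors; INNOVATE and REFINE learn payoffs exactly. Under the
model-bias extension the entry's `observe_who` function receives
Poisson-noised performance indices (age, total payoff, times observed,
offspring count — all four noised, since all are social information) for
every available model, in randomized order, and its ranking's first
`n_observe` become the models.

A strategy that raises an exception or returns an illegal decision
(unknown move, REFINE outside the cumulative extension, EXPLOIT/REFINE on
an unknown behavior) forfeits the round: no payoff, no learning, and the
round still counts toward its age. `strict` mode aborts instead, which the
test suite uses to prove the reference entries never emit illegal moves.

## Demography, migration, scoring

Death-birth selection: each agent independently dies with probability
`death_prob = 0.02` per round (so the number of deaths is Binomial, not
fixed, and lifetimes are geometric with mean 50). Each vacancy is filled
by the offspring of a same-deme *survivor* of that round's death draw,
selected with probability `P_z / Σ P_i` where `P_z` is mean lifetime
EXPLOIT payoff; if all weights are zero the draw is uniform, and if an
entire deme died its pre-death members stand in. Newborns are naive and
act from the next round. Mutation (probability 1/50 per birth) reassigns a
uniformly random registered entry other than the parent's; in invasion
protocols the mutation target set is restricted to the invader, so the
invader can re-enter after stochastic loss. Mutation is disabled during
the scoring window.

Migration (spatial runs) draws `n_migrate` agents uniformly from each deme
and reassigns each to a uniformly chosen *different* deme, repertoires and
refinement levels intact; recorded payoffs are then stale against the new
deme's table. Because destinations are random, per-deme sizes are constant
only in expectation while total population size is conserved exactly.
`n_migrate` defaults to 5 — a modest 5%-per-round flow at the low end of
the melee range 1–20 (the pairwise-stage value is not independently
constrained).

Scores are mean last-window frequencies with the window equal to the final
`ceil(rounds/4)` rounds; the same window gates the mutation shut-off. The
full loop order per round is: moves → reproduction → environmental change →
migration.

## Reference strategies

* `innovateOnce` — INNOVATE once, then EXPLOIT that behavior for life; the
  standard melee defender.
* `observeExploit` — the blind copier: OBSERVE until the repertoire is
  non-empty (a failed or model-less observation teaches nothing, and an
  empty-repertoire agent has no legal EXPLOIT, so it observes again), then
  EXPLOIT the best-recorded behavior forever.
* `smartRefiner(refine_budget, age_window, payoff_threshold)` — a
  parametric family of conditional refiners: observe while naive, then
  REFINE the best-known behavior while (a) its recorded payoff is below
  `payoff_threshold`, (b) the agent is within its first `age_window`
  rounds, and (c) fewer than `refine_budget` REFINEs have been played;
  otherwise EXPLOIT. Defaults: budget 10 (≈ the number of increments that
  lifts a fresh behavior past the best basic payoff), window 30 (refining
  later in an expected 50-round life leaves too little time to recoup),
  threshold 60 (just above the ceiling of typical basic payoffs).
* `payoffBiasObserver` — the blind copier plus the reference `observe_who`
  ranking: models ordered by estimated total payoff per round of life
  (raw total when the age estimate is zero), random tie-break.

The original 51 submitted tournament entries were never published; the two
protocol-defined entries above are faithful to their definitions, and the
`smartRefiner` family is an explicit stand-in for the conditional refiners.
Entries are pure functions of their view plus an engine-supplied random
stream, so recorded decision sequences replay exactly.

## The stopping-criterion experiment

`refinement_stopping_experiment` contrasts "smart refiner" entries with
the blind copier: cumulative melee runs (resident `innovateOnce`, both
classes invading by mutation) halt the first round the mean refinement
level of the *performed* behaviors (non-forfeited EXPLOITs) exceeds a
stopping level, and each class's mean lifetime payoff is recorded at that
instant; runs that never reach the level are censored.

The default smart roster (`DEFAULT_SMART_ROSTER`) uses `smartRefiner`
variants with budgets 5–15, windows 20–40 and `payoff_threshold = 150` —
near the total-payoff ceiling (`p_max` + a high basic payoff), so these
entries behave as budgeted early-life refiners that keep refining even in
already-refined worlds. That choice is deliberate: a threshold at the
*basic*-payoff ceiling makes an entry cease refining once increments alone
exceed it, which (i) stalls population refinement near that point and
(ii) removes the very cost that makes refiners invadable — the adaptation
that distinguished the tournament's winner from the other conditional
refiners. With the default roster the experiment reproduces the expected
crossover: refiners out-earn blind copiers when the world is still
unrefined (their early increments are large and their refined behavior
beats anything copyable), while at high refinement levels the copier wins
(a newborn copies the refined behavior immediately and skips the refine
rounds, whose increments are by then tiny).

The default experiment condition is `p_c = 0.1` with stopping levels
spanning ~1–60 and a 3,000-round censoring horizon — sizes chosen so a
50-replicate-per-level experiment completes in minutes on one core while
leaving the crossover unambiguous.

## What the synthetic world does and does not show

All inputs are generated internally from the stated distributions; there
is no external data. The generator reproduces the study conditions —
payoff distribution, restlessness, Poisson observation noise, demography —
but agents' "behaviors" have no internal structure: no recombination of
variants, no behavior-specific learning costs, no correlated payoff
dynamics, and refinement always helps. Passing tests therefore certify the
engine's contracts and the model's internal logic (selection, invasion,
diversity collapse under cumulative culture), not claims about any
empirical learning system.

## Numerical conventions and scaling

* Increments are precomputed per `(r_max, p_max)` as a lookup table; the
  closed form is tested against direct series summation at 1e-9 relative
  tolerance for `r_max` up to 1000.
* Pielou evenness uses `S = 100` possible behaviors (the only reading
  under which J = 1 for all-possible-equal and J = 0 for a monoculture
  simultaneously hold) with `0·ln 0 := 0`, and is undefined (NaN) for an
  all-zero count vector. Knowledge evenness uses proportions of agents
  knowing each behavior, the natural analogue of the usage definition.
* Persistence pools maximal presence runs over behaviors, per deme, then
  averages deme summaries; refinement level is not differentiated. Both
  whole-run and windowed computations are available; whole-run is the
  default. Diversity and usage snapshots are taken at the same post-move,
  pre-reproduction instant each round, so "exploited implies known" holds
  exactly; time-series output is block-averaged at a 1,000-round cadence.
* One root seed drives named substreams (environment, moves, demography,
  migration, observation, strategies) derived with fixed spawn keys, so
  adding a component never perturbs the others and every run, contest and
  schedule is a pure function of its seed. Child seeds are kept below 2³¹.
* Tests and shipped experiment defaults use scaled-down sizes (hundreds to
  a few thousand rounds, tens of replicates) chosen as the smallest sizes
  at which the targeted effects are statistically unambiguous; the full
  10,000-round, full-grid protocols remain available through configuration.

## Known limitations

Single-process execution (replicates are independent given their seeds and
can be farmed out externally); no fecundity selection, overlapping
generations or group payoff structure; the exponential parameter draws for
the melee stages fix their rates at the midpoints of the systematic ranges
(the original distributions are not independently constrained); and the
`smartRefiner` family is a documented surrogate, not a reconstruction of
any submitted entry.
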