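"""Agent state and the resolution of one simulation round.

Each round every living agent submits one of four moves:

* ``EXPLOIT``  — perform a known behavior and collect its current payoff
  (the only payoff-earning move); the received payoff replaces the
  recorded one.
* ``INNOVATE`` — learn a uniformly random unknown behavior with its
  exact current basic payoff, at refinement level 0.
* ``OBSERVE``  — copy the behavior(s) of up to ``n_observe`` agents that
  exploited in the same deme this round.  Each copying event fails
  independently with probability ``p_copyFail``; successful copies carry
  the model's refinement level but a Poisson-noised payoff estimate.
* ``REFINE``   — (cumulative extension only) raise a known behavior's
  refinement level by one and learn its new total payoff exactly.

Moves are resolved in two phases, so the order in which agents are
queried never affects who is available to copy: first all decisions are
collected and EXPLOIT/INNOVATE/REFINE applied, then OBSERVE moves are
processed against the round's pool of same-deme exploiters.

A strategy that raises or returns an illegal decision forfeits the
round: no payoff, no learning, and the round still counts towards its
age (``strict`` mode aborts instead).

Refinement levels are engine-visible but hidden from strategies: the
:class:`StrategyView` handed to a strategy's ``move`` function exposes
the agent's own history, repertoire payoffs, migration history and the
simulation parameters — never refinement levels, the true payoff tables
or other agents' private state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, NamedTuple

import numpy as np

from .environment import BanditEnvironment

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig
    from .strategies import Strategy

EXPLOIT = "EXPLOIT"
INNOVATE = "INNOVATE"
OBSERVE = "OBSERVE"
REFINE = "REFINE"
MOVES = frozenset((EXPLOIT, INNOVATE, OBSERVE, REFINE))


class MoveDecision(NamedTuple):
    """A strategy's decision: the move, plus the behavior it applies to.

    ``behavior`` is required for EXPLOIT and REFINE and ignored for
    INNOVATE and OBSERVE.
    """

    move: str
    behavior: int | None = None


class RepertoireEntry:
    """One known behavior: recorded payoff + hidden refinement level.

    ``recorded_payoff`` is the last value learned, observed or received
    for this behavior; it may be stale (environment changed) or noisy
    (acquired through OBSERVE).  ``refinement_level`` is only ever seen
    by the engine.
    """

    __slots__ = ("behavior", "recorded_payoff", "refinement_level")

    def __init__(self, behavior: int, recorded_payoff: float, refinement_level: int = 0):
        self.behavior = behavior
        self.recorded_payoff = recorded_payoff
        self.refinement_level = refinement_level

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RepertoireEntry({self.behavior}, payoff={self.recorded_payoff:.3g}, "
            f"r={self.refinement_level})"
        )


class Agent:
    """One individual: strategy binding, repertoire, lifetime accounting.

    Agents are born naive (empty repertoire) and keep aligned per-round
    history lists (move, behavior(s), payoff(s)/estimate(s), deme,
    migration flag).  ``mean_lifetime_payoff`` is the reproduction
    weight P_z = total EXPLOIT payoff / rounds alive.
    """

    __slots__ = (
        "agent_id",
        "entry_id",
        "deme",
        "birth_round",
        "rounds_alive",
        "repertoire",
        "total_exploit_payoff",
        "times_observed",
        "n_offspring",
        "n_forfeits",
        "moves",
        "behaviors",
        "payoffs",
        "demes",
        "migrations",
        "_migrated_pending",
    )

    def __init__(self, agent_id: int, entry_id: str, deme: int, birth_round: int = 0):
        self.agent_id = agent_id
        self.entry_id = entry_id
        self.deme = deme
        self.birth_round = birth_round
        self.rounds_alive = 0
        self.repertoire: dict[int, RepertoireEntry] = {}
        self.total_exploit_payoff = 0.0
        self.times_observed = 0
        self.n_offspring = 0
        self.n_forfeits = 0
        self.moves: list[str] = []
        self.behaviors: list = []
        self.payoffs: list = []
        self.demes: list[int] = []
        self.migrations: list[bool] = []
        self._migrated_pending = False

    @property
    def mean_lifetime_payoff(self) -> float:
        """P_z: summed EXPLOIT payoffs over rounds alive (0 for newborns)."""
        if self.rounds_alive == 0:
            return 0.0
        return self.total_exploit_payoff / self.rounds_alive

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Agent(id={self.agent_id}, entry={self.entry_id!r}, deme={self.deme}, "
            f"age={self.rounds_alive}, |rep|={len(self.repertoire)})"
        )


class StrategyView:
    """The information a strategy is allowed to see.

    History lists are the agent's live lists for speed; strategies must
    treat them as read-only (entries may not persist state anywhere but
    are free to recompute from the view each round).
    """

    __slots__ = (
        "rounds_alive",
        "moves",
        "behaviors",
        "payoffs",
        "demes",
        "migrations",
        "repertoire",
        "params",
    )

    def __init__(self, agent: Agent, params: "SimulationConfig"):
        self.rounds_alive = agent.rounds_alive
        self.moves = agent.moves
        self.behaviors = agent.behaviors
        self.payoffs = agent.payoffs
        self.demes = agent.demes
        self.migrations = agent.migrations
        self.repertoire = {b: e.recorded_payoff for b, e in agent.repertoire.items()}
        self.params = params


class ModelInfo(NamedTuple):
    """Poisson-noised public information about one available model.

    Passed (in randomized order) to an entry's ``observe_who`` ranking
    function under the model-bias extension.  ``model_ref`` is an opaque
    handle; every other field is a noisy non-negative integer estimate
    of the true value.
    """

    model_ref: int
    age_estimate: int
    total_payoff_estimate: int
    times_observed_estimate: int
    n_offspring_estimate: int


class ExploitRecord(NamedTuple):
    """A non-forfeited EXPLOIT this round: who, what, and at what payoff."""

    agent: Agent
    behavior: int
    payoff: float
    refinement_level: int


@dataclass
class RoundOutcome:
    """Per-round aggregates emitted by :func:`resolve_round`."""

    exploiters_by_deme: dict[int, list[ExploitRecord]]
    move_counts: dict[str, int]
    forfeits: list[tuple[int, str]]  # (agent_id, reason)
    mean_refinement_performed: float  # NaN if nobody exploited
    behavior_usage: np.ndarray  # (n_demes, n_behaviors) exploiter counts


class ForfeitError(RuntimeError):
    """Raised in strict mode when a strategy misbehaves."""


def apply_exploit(
    agent: Agent, behavior: int, env: BanditEnvironment, inc_table: np.ndarray
) -> float:
    """Perform a known behavior; returns the payoff received.

    The payoff is the behavior's *current* basic payoff in the agent's
    deme plus the increment for the agent's private refinement level;
    the recorded payoff is corrected to the received value.
    """
    entry = agent.repertoire[behavior]
    payoff = float(env.payoffs[agent.deme, behavior]) + inc_table[entry.refinement_level]
    entry.recorded_payoff = payoff
    agent.total_exploit_payoff += payoff
    return payoff


def apply_innovate(
    agent: Agent, env: BanditEnvironment, rng: np.random.Generator
) -> int | None:
    """Learn a uniformly random unknown behavior with its exact payoff.

    Returns the behavior learned, or None when the repertoire already
    holds all behaviors (the move then teaches nothing).
    """
    n = env.n_behaviors
    known = agent.repertoire
    n_known = len(known)
    if n_known >= n:
        return None
    if n_known < n // 2:
        # Rejection sampling is cheap while the repertoire is small.
        while True:
            b = int(rng.integers(n))
            if b not in known:
                break
    else:
        unknown = [b for b in range(n) if b not in known]
        b = unknown[int(rng.integers(len(unknown)))]
    known[b] = RepertoireEntry(b, float(env.payoffs[agent.deme, b]), 0)
    return b


def apply_refine(
    agent: Agent, behavior: int, env: BanditEnvironment, inc_table: np.ndarray, r_max: int
) -> float:
    """Raise a known behavior's refinement level by one (capped at r_max).

    The agent learns the new total payoff exactly but never the level
    itself.  Returns the new total payoff.
    """
    entry = agent.repertoire[behavior]
    if entry.refinement_level < r_max:
        entry.refinement_level += 1
    payoff = float(env.payoffs[agent.deme, behavior]) + inc_table[entry.refinement_level]
    entry.recorded_payoff = payoff
    return payoff


def build_model_info(
    pool: list[ExploitRecord], rng: np.random.Generator
) -> list[ModelInfo]:
    """Noisy public info for every available model, in randomized order.

    All four performance indices (age, total payoff, times observed,
    number of offspring) are drawn from Poisson distributions with mean
    equal to the true value; ``model_ref`` indexes into ``pool``.
    """
    order = rng.permutation(len(pool))
    infos = []
    for i in order:
        m = pool[int(i)].agent
        infos.append(
            ModelInfo(
                model_ref=int(i),
                age_estimate=int(rng.poisson(m.rounds_alive)),
                total_payoff_estimate=int(rng.poisson(m.total_exploit_payoff)),
                times_observed_estimate=int(rng.poisson(m.times_observed)),
                n_offspring_estimate=int(rng.poisson(m.n_offspring)),
            )
        )
    return infos


def apply_observe(
    agent: Agent,
    pool: list[ExploitRecord],
    cfg: "SimulationConfig",
    strategy: "Strategy",
    rng_obs: np.random.Generator,
    rng_strat: np.random.Generator,
) -> list[tuple[int, float]]:
    """Process one OBSERVE move; returns the (behavior, estimate) copies.

    Up to ``n_observe`` distinct models are sampled from the same-deme
    exploiter pool — uniformly without replacement, or ranked by the
    entry's ``observe_who`` under the model-bias extension.  Each event
    independently fails with probability ``p_copyFail`` (and is then
    consumed: nothing is learned from that model).  A successful copy
    installs the model's behavior at the model's refinement level with
    a Poisson(true received payoff) estimate, overwriting any existing
    record, and increments the model's times-observed counter.
    """
    if not pool:
        return []
    n_observe = cfg.n_observe
    if cfg.model_bias_enabled and strategy.observe_who is not None:
        infos = build_model_info(pool, rng_obs)
        ranked = strategy.observe_who(infos, rng_strat)
        selected = [pool[info.model_ref] for info in ranked[:n_observe]]
    elif len(pool) <= n_observe:
        selected = pool
    else:
        idx = rng_obs.choice(len(pool), size=n_observe, replace=False)
        selected = [pool[int(i)] for i in idx]

    learned: list[tuple[int, float]] = []
    p_fail = cfg.p_copyFail
    for rec in selected:
        if p_fail > 0.0 and rng_obs.random() < p_fail:
            continue
        estimate = float(rng_obs.poisson(rec.payoff))
        agent.repertoire[rec.behavior] = RepertoireEntry(
            rec.behavior, estimate, rec.refinement_level
        )
        rec.agent.times_observed += 1
        learned.append((rec.behavior, estimate))
    return learned


def resolve_round(
    population: list[Agent],
    env: BanditEnvironment,
    cfg: "SimulationConfig",
    strategies: dict[str, "Strategy"],
    inc_table: np.ndarray,
    rng_moves: np.random.Generator,
    rng_obs: np.random.Generator,
    rng_strat: np.random.Generator,
    move_log: list | None = None,
    round_index: int = 0,
) -> RoundOutcome:
    """Resolve one full round of moves for the whole population.

    Phase 1 queries every agent's strategy against its pre-round view
    and applies EXPLOIT, INNOVATE and REFINE; phase 2 processes OBSERVE
    moves against the pool of this round's same-deme non-forfeited
    exploiters.  Histories are appended, ages incremented.
    """
    exploiters_by_deme: dict[int, list[ExploitRecord]] = {}
    observers: list[tuple[Agent, "Strategy"]] = []
    move_counts = {EXPLOIT: 0, INNOVATE: 0, OBSERVE: 0, REFINE: 0}
    forfeits: list[tuple[int, str]] = []
    usage = np.zeros((env.n_demes, env.n_behaviors), dtype=np.int32)
    ref_sum = 0.0
    ref_n = 0
    cumulative_on = cfg.cumulative_enabled

    for agent in population:
        agent.demes.append(agent.deme)
        agent.migrations.append(agent._migrated_pending)
        agent._migrated_pending = False

        strategy = strategies[agent.entry_id]
        view = StrategyView(agent, cfg)
        reason: str | None = None
        decision: MoveDecision | None = None
        try:
            decision = strategy.move(view, rng_strat)
        except Exception as exc:  # noqa: BLE001 — strategy code is untrusted
            reason = f"strategy error: {exc!r}"

        move = None
        behavior = None
        payoff = None
        if reason is None:
            if isinstance(decision, str):
                move, behavior = decision, None
            else:
                try:
                    move = decision[0]
                    behavior = decision[1] if len(decision) > 1 else None
                except (TypeError, IndexError):
                    move = None
            if move not in MOVES:
                reason = f"unknown move {move!r}"
            elif move == REFINE and not cumulative_on:
                reason = "REFINE outside the cumulative extension"
            elif move in (EXPLOIT, REFINE) and behavior not in agent.repertoire:
                reason = f"{move} on behavior not in repertoire"

        if reason is not None:
            if cfg.strict:
                raise ForfeitError(f"agent {agent.agent_id} ({agent.entry_id}): {reason}")
            forfeits.append((agent.agent_id, reason))
            agent.n_forfeits += 1
            agent.moves.append("FORFEIT")
            agent.behaviors.append(None)
            agent.payoffs.append(None)
        elif move == EXPLOIT:
            level = agent.repertoire[behavior].refinement_level
            payoff = apply_exploit(agent, behavior, env, inc_table)
            exploiters_by_deme.setdefault(agent.deme, []).append(
                ExploitRecord(agent, behavior, payoff, level)
            )
            usage[agent.deme, behavior] += 1
            ref_sum += level
            ref_n += 1
            move_counts[EXPLOIT] += 1
            agent.moves.append(EXPLOIT)
            agent.behaviors.append(behavior)
            agent.payoffs.append(payoff)
        elif move == INNOVATE:
            learned = apply_innovate(agent, env, rng_moves)
            move_counts[INNOVATE] += 1
            agent.moves.append(INNOVATE)
            agent.behaviors.append(learned)
            agent.payoffs.append(
                agent.repertoire[learned].recorded_payoff if learned is not None else None
            )
        elif move == REFINE:
            payoff = apply_refine(agent, behavior, env, inc_table, cfg.r_max)
            move_counts[REFINE] += 1
            agent.moves.append(REFINE)
            agent.behaviors.append(behavior)
            agent.payoffs.append(payoff)
        else:  # OBSERVE — deferred to phase 2
            observers.append((agent, strategy))

        if move_log is not None and move != OBSERVE:
            move_log.append(
                (
                    round_index,
                    agent.agent_id,
                    agent.entry_id,
                    agent.deme,
                    agent.moves[-1],
                    behavior,
                    payoff,
                    reason is not None,
                )
            )

    for agent, strategy in observers:
        pool = exploiters_by_deme.get(agent.deme, [])
        learned = apply_observe(agent, pool, cfg, strategy, rng_obs, rng_strat)
        move_counts[OBSERVE] += 1
        agent.moves.append(OBSERVE)
        agent.behaviors.append(tuple(b for b, _ in learned))
        agent.payoffs.append(tuple(p for _, p in learned))
        if move_log is not None:
            move_log.append(
                (
                    round_index,
                    agent.agent_id,
                    agent.entry_id,
                    agent.deme,
                    OBSERVE,
                    None,
                    None,
                    False,
                )
            )

    for agent in population:
        agent.rounds_alive += 1

    return RoundOutcome(
        exploiters_by_deme=exploiters_by_deme,
        move_counts=move_counts,
        forfeits=forfeits,
        mean_refinement_performed=(ref_sum / ref_n) if ref_n else float("nan"),
        behavior_usage=usage,
    )
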