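"""The evolutionary simulation loop.

Each round applies, in order: (i) move resolution for every agent,
(ii) death-birth reproduction, (iii) environmental change, and (iv) —
under spatial structure — migration between demes.

Demography is a death-birth process: every agent independently dies
with probability ``death_prob`` (0.02 by default, expected lifespan 50
rounds) and each vacancy is refilled by the offspring of a same-deme
survivor drawn with probability P_z / sum_i P_i, where P_z is the mean
lifetime EXPLOIT payoff.  Offspring are naive and inherit the parent's
entry unless mutation (probability 1/50 per birth) reassigns a
uniformly random other registered entry; mutation is switched off
during the final scoring window.  An entry's score in a run is its
mean population frequency over that window (the last quarter of the
run by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .agents import Agent, RoundOutcome, resolve_round
from .config import SimulationConfig
from .environment import BanditEnvironment, RefinementConfig, increment_table
from .rng import make_streams
from .strategies import Strategy

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "RunResult",
    "step",
    "death_birth",
    "migrate",
    "run_simulation",
]


@dataclass
class SimulationState:
    """Mutable state of a running simulation."""

    cfg: SimulationConfig
    env: BanditEnvironment
    population: list[Agent]
    strategies: dict[str, Strategy]
    rngs: dict[str, np.random.Generator]
    inc_table: np.ndarray
    round: int = 0
    next_agent_id: int = 0
    max_refinement: int = 0
    stopped: bool = False
    death_lifetimes: list[int] = field(default_factory=list)
    mutation_events: int = 0
    payoff_by_entry: dict[str, float] = field(default_factory=dict)

    def new_agent(self, entry_id: str, deme: int) -> Agent:
        agent = Agent(self.next_agent_id, entry_id, deme, birth_round=self.round)
        self.next_agent_id += 1
        return agent


def _init_state(
    cfg: SimulationConfig,
    strategies: dict[str, Strategy],
    initial: str | dict[str, int],
    rngs: dict[str, np.random.Generator],
) -> SimulationState:
    ref_cfg = RefinementConfig(r_max=cfg.r_max, p_max=cfg.p_max)
    env = BanditEnvironment.generate(
        cfg.n_behaviors, cfg.n_demes, cfg.p_c, rngs["environment"]
    )
    state = SimulationState(
        cfg=cfg,
        env=env,
        population=[],
        strategies=strategies,
        rngs=rngs,
        inc_table=increment_table(ref_cfg),
    )
    if isinstance(initial, str):
        composition = {initial: cfg.n_agents}
    else:
        composition = dict(initial)
        if sum(composition.values()) != cfg.n_agents:
            raise ValueError("initial composition must total n_agents per deme")
    for deme in range(cfg.n_demes):
        for entry_id, count in composition.items():
            if entry_id not in strategies:
                raise KeyError(f"initial entry {entry_id!r} not registered")
            for _ in range(count):
                state.population.append(state.new_agent(entry_id, deme))
    return state


def death_birth(
    state: SimulationState,
    mutation_active: bool,
    mutation_targets: list[str] | None,
) -> int:
    """One death-birth step; returns the number of deaths.

    Deaths are independent coins per agent (Binomial count, not fixed).
    The parent pool for each vacancy is the same-deme survivors of this
    round's death draw, weighted by mean lifetime payoff; if every
    weight is zero the draw is uniform, and if a whole deme died the
    pre-death members stand in as parents.  Mutation candidates are the
    registered entries other than the parent's — or, when
    ``mutation_targets`` is given (invasion protocols), that set minus
    the parent's entry.
    """
    cfg = state.cfg
    rng = state.rngs["demography"]
    p = cfg.death_prob
    if p <= 0.0:
        return 0
    population = state.population
    registered = list(state.strategies)

    u = rng.random(len(population))
    dead_idx = [i for i, ui in enumerate(u) if ui < p]
    if not dead_idx:
        return 0

    dead_set = set(dead_idx)
    survivors_by_deme: dict[int, list[Agent]] = {}
    members_by_deme: dict[int, list[Agent]] = {}
    for i, agent in enumerate(population):
        members_by_deme.setdefault(agent.deme, []).append(agent)
        if i not in dead_set:
            survivors_by_deme.setdefault(agent.deme, []).append(agent)

    # Per-deme cumulative reproduction weights, built once per round.
    cumw: dict[int, tuple[list[Agent], np.ndarray | None]] = {}
    for deme, members in members_by_deme.items():
        pool = survivors_by_deme.get(deme, members)
        w = np.fromiter(
            (a.mean_lifetime_payoff for a in pool), dtype=np.float64, count=len(pool)
        )
        total = w.sum()
        cumw[deme] = (pool, np.cumsum(w) / total if total > 0.0 else None)

    for i in dead_idx:
        dying = population[i]
        state.death_lifetimes.append(dying.rounds_alive)
        pool, cum = cumw[dying.deme]
        if cum is None:
            parent = pool[int(rng.integers(len(pool)))]
        else:
            parent = pool[int(np.searchsorted(cum, rng.random(), side="right"))]
        entry_id = parent.entry_id
        if mutation_active and rng.random() < cfg.mutation_prob:
            if mutation_targets is None:
                candidates = [e for e in registered if e != entry_id]
            else:
                candidates = [e for e in mutation_targets if e != entry_id]
            if candidates:
                entry_id = candidates[int(rng.integers(len(candidates)))]
                state.mutation_events += 1
        parent.n_offspring += 1
        population[i] = state.new_agent(entry_id, dying.deme)
    return len(dead_idx)


def migrate(state: SimulationState) -> int:
    """Random migration between demes; returns the number of migrants.

    ``n_migrate`` agents are drawn uniformly from each deme (all of
    them when the deme is smaller) and each is reassigned to a
    uniformly chosen *different* deme.  Repertoires — including
    refinement levels — travel unchanged, so recorded payoffs become
    stale against the new deme's payoff table.
    """
    cfg = state.cfg
    if not cfg.spatial_enabled or cfg.n_migrate <= 0 or cfg.n_demes < 2:
        return 0
    rng = state.rngs["migration"]
    by_deme: dict[int, list[Agent]] = {}
    for agent in state.population:
        by_deme.setdefault(agent.deme, []).append(agent)

    moves: list[tuple[Agent, int]] = []
    for deme in sorted(by_deme):
        members = by_deme[deme]
        k = min(cfg.n_migrate, len(members))
        if k == 0:
            continue
        chosen = rng.choice(len(members), size=k, replace=False)
        others = [d for d in range(cfg.n_demes) if d != deme]
        for i in chosen:
            moves.append((members[int(i)], others[int(rng.integers(len(others)))]))
    for agent, new_deme in moves:  # applied simultaneously
        agent.deme = new_deme
        agent._migrated_pending = True
    return len(moves)


def step(
    state: SimulationState,
    mutation_active: bool = True,
    mutation_targets: list[str] | None = None,
    move_log: list | None = None,
    stop_condition: Callable[["SimulationState", RoundOutcome], bool] | None = None,
    diversity: list | None = None,
) -> RoundOutcome:
    """Advance the simulation one round (moves, births, change, migration).

    A firing ``stop_condition`` (checked right after move resolution)
    halts the round before reproduction, environmental change and
    migration, so per-agent fitness can be read at that instant; the
    state is then flagged ``stopped``.  When ``diversity`` is a list, a
    (behavior-usage, knowledge) count pair is appended to it at the
    same post-move instant, so the two snapshots describe the same
    population (exploited implies known).
    """
    cfg = state.cfg
    outcome = resolve_round(
        state.population,
        state.env,
        cfg,
        state.strategies,
        state.inc_table,
        state.rngs["moves"],
        state.rngs["observation"],
        state.rngs["strategies"],
        move_log=move_log,
        round_index=state.round,
    )
    if diversity is not None:
        diversity.append(
            (
                outcome.behavior_usage,
                _knowledge_counts(state.population, cfg.n_demes, cfg.n_behaviors),
            )
        )
    for records in outcome.exploiters_by_deme.values():
        for rec in records:
            if rec.refinement_level > state.max_refinement:
                state.max_refinement = rec.refinement_level
            acc = state.payoff_by_entry
            acc[rec.agent.entry_id] = acc.get(rec.agent.entry_id, 0.0) + rec.payoff
    if stop_condition is not None and stop_condition(state, outcome):
        state.stopped = True
        state.round += 1
        return outcome
    death_birth(state, mutation_active, mutation_targets)
    state.env.change_(state.rngs["environment"])
    migrate(state)
    state.round += 1
    return outcome


@dataclass
class RunResult:
    """Everything recorded from one simulation run."""

    scores: dict[str, float]
    rounds_run: int
    stopped_round: int | None
    max_refinement: int
    final_counts: dict[str, int]
    payoff_by_entry: dict[str, float]
    death_lifetimes: list[int]
    population_fitness: list[tuple[str, float]]  # (entry_id, P_z) at end/stop
    mean_refinement_series: np.ndarray | None = None
    composition: pd.DataFrame | None = None
    behavior_counts: np.ndarray | None = None  # (rounds, demes, behaviors)
    knowledge_counts: np.ndarray | None = None
    move_log: pd.DataFrame | None = None
    mutation_events: int = 0

    def composition_long(self) -> pd.DataFrame:
        """Trajectory in long format (round, entry_id, frequency)."""
        if self.composition is None:
            raise ValueError("run was executed without composition recording")
        return self.composition


MOVE_LOG_COLUMNS = [
    "round",
    "agent_id",
    "entry_id",
    "deme",
    "move",
    "behavior",
    "payoff",
    "forfeited",
]


def _knowledge_counts(population: list[Agent], n_demes: int, n_behaviors: int) -> np.ndarray:
    counts = np.zeros((n_demes, n_behaviors), dtype=np.int32)
    for agent in population:
        row = counts[agent.deme]
        for b in agent.repertoire:
            row[b] += 1
    return counts


def run_simulation(
    cfg: SimulationConfig,
    strategies: dict[str, Strategy],
    initial: str | dict[str, int],
    *,
    seed: int | None = None,
    rounds: int | None = None,
    mutation_start: int = 0,
    mutation_targets: list[str] | None = None,
    stop_condition: Callable[[SimulationState, RoundOutcome], bool] | None = None,
    record_composition: bool = False,
    record_diversity: bool = False,
    record_moves: bool = False,
) -> RunResult:
    """Run a full simulation and score every registered entry.

    ``initial`` seeds each deme with a monoculture (entry name) or a
    per-deme composition (entry -> count).  Mutation operates from
    round ``mutation_start`` (e.g. after an invasion burn-in) until the
    scoring window opens.  ``stop_condition`` is evaluated right after
    move resolution each round; when it fires the run halts immediately
    and per-agent fitness is captured at that instant.

    Scores are mean last-window frequencies; they are 0 for entries
    extinct through the window and sum to 1 across entries whenever
    the window was reached.
    """
    rounds = cfg.rounds if rounds is None else rounds
    root_seed = cfg.seed if seed is None else seed
    if root_seed is None:
        raise ValueError("a seed is required (cfg.seed or seed=)")
    rngs = make_streams(root_seed)
    state = _init_state(cfg, strategies, initial, rngs)

    window_start = cfg.score_window_start(rounds)
    n_total = len(state.population)
    freq_sum: dict[str, float] = {e: 0.0 for e in strategies}
    window_rounds = 0

    comp_rows: list[tuple[int, str, int]] = []
    diversity: list | None = [] if record_diversity else None
    ref_series: list[float] = []
    move_log: list | None = [] if record_moves else None
    stopped_round: int | None = None

    for t in range(rounds):
        mutation_active = (t >= mutation_start) and (t < window_start)
        outcome = step(
            state, mutation_active, mutation_targets, move_log, stop_condition, diversity
        )
        ref_series.append(outcome.mean_refinement_performed)

        counts: dict[str, int] = {}
        for agent in state.population:
            counts[agent.entry_id] = counts.get(agent.entry_id, 0) + 1
        if record_composition:
            for entry_id, c in counts.items():
                comp_rows.append((t, entry_id, c))
        if t >= window_start:
            window_rounds += 1
            for entry_id, c in counts.items():
                freq_sum[entry_id] += c / n_total

        if state.stopped:
            stopped_round = t
            break

    scores = {
        e: (freq_sum[e] / window_rounds if window_rounds else float("nan"))
        for e in strategies
    }
    final_counts: dict[str, int] = {e: 0 for e in strategies}
    for agent in state.population:
        final_counts[agent.entry_id] += 1

    composition = None
    if record_composition:
        composition = pd.DataFrame(comp_rows, columns=["round", "entry_id", "count"])
        composition["frequency"] = composition["count"] / n_total

    return RunResult(
        scores=scores,
        rounds_run=stopped_round + 1 if stopped_round is not None else rounds,
        stopped_round=stopped_round,
        max_refinement=state.max_refinement,
        final_counts=final_counts,
        payoff_by_entry=dict(state.payoff_by_entry),
        death_lifetimes=state.death_lifetimes,
        population_fitness=[
            (a.entry_id, a.mean_lifetime_payoff) for a in state.population
        ],
        mean_refinement_series=np.asarray(ref_series, dtype=np.float64),
        composition=composition,
        behavior_counts=np.stack([d[0] for d in diversity]) if diversity else None,
        knowledge_counts=np.stack([d[1] for d in diversity]) if diversity else None,
        move_log=(
            pd.DataFrame(move_log, columns=MOVE_LOG_COLUMNS) if record_moves else None
        ),
        mutation_events=state.mutation_events,
    )
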