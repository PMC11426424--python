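"""The three-stage contest protocol and the refiner-vs-copier experiment.

Stage 1 (pairwise invasion): for every ordered pair of entries, a
monoculture of the defender runs for a 100-round burn-in, after which
the invader can enter through mutation (and re-enter after stochastic
loss).  Each unordered pair is contested under 6 parameter sets
(p_c in {0.001, 0.01, 0.1} x n_observe in {1, 5}; r_max = 100,
p_copyFail = 0.05), twice per invasion direction: 24 simulations per
pair, 2,550 ordered contests for 51 entries.

Stage 2 (single-extension melee): all entries simultaneously invade a
resident population of the standard defender ``innovateOnce``, across a
systematic grid (7 p_c x 7 p_copyFail x 4 n_observe x 6 r_max values)
with replicates, plus runs whose parameters are drawn from truncated
exponential distributions.  Stage 3 repeats the melee with all three
extensions active at once.

An entry's score in a simulation is its mean population frequency over
the last quarter; stage scores average over simulations.

The stopping-criterion experiment contrasts "smart refiner" entries
with the blind copier: melee-style cumulative runs are halted the
first round the mean refinement level of the behaviors performed
exceeds a stopping level, and the mean lifetime payoff of each class
of agents is recorded at that instant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .dynamics import RunResult, run_simulation
from .rng import derive_seed
from .strategies import Strategy, innovate_once

__all__ = [
    "ContestSpec",
    "stage1_parameter_sets",
    "pairwise_schedule",
    "run_invasion_contest",
    "pairwise_stage",
    "STAGE2_GRID",
    "melee_grid",
    "draw_melee_params",
    "melee_stage",
    "refinement_stopping_experiment",
    "classify_environment",
    "select_top",
]

STAGE1_P_C = (0.001, 0.01, 0.1)
STAGE1_N_OBSERVE = (1, 5)
STAGE1_FIXED = dict(r_max=100, p_copyFail=0.05)

STAGE2_GRID: dict[str, tuple] = {
    "p_c": (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.4),
    "p_copyFail": (0.0, 0.01, 0.05, 0.1, 0.15, 0.25, 0.5),
    "n_observe": (1, 2, 5, 10),
    "r_max": (10, 25, 50, 100, 500, 1000),
}

#: Ranges used for the exponential parameter draws (min, max); rates are
#: set so the distribution mean sits at the midpoint of each range, and
#: draws are resampled into the range.
MELEE_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "p_c": (0.001, 0.4),
    "p_copyFail": (0.0, 0.5),
    "n_observe": (1, 10),
    "r_max": (10, 1000),
    "n_migrate": (1, 20),
}


#: Default "smart refiner" roster for the stopping-criterion experiment:
#: budgeted early-life refiners whose payoff threshold sits near the
#: total-payoff ceiling, so they keep refining in already-refined worlds
#: (the trait that made the original conditional refiners invadable by
#: blind copiers at high refinement levels).
DEFAULT_SMART_ROSTER: tuple[str, ...] = (
    "smartRefiner_b10_w30_t150",
    "smartRefiner_b15_w40_t150",
    "smartRefiner_b5_w20_t150",
)


@dataclass(frozen=True)
class ContestSpec:
    """One scheduled contest (a single simulation or replicate set)."""

    defender: str
    invader: str | tuple[str, ...]
    extension: str
    params: tuple[tuple[str, float], ...]  # sorted (name, value) pairs
    replicate: int
    burn_in: int = 100
    seed: int = 0

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


def stage1_parameter_sets(extension: str) -> list[dict]:
    """The 6 pairwise-stage parameter sets for one extension."""
    sets = []
    for p_c, n_observe in itertools.product(STAGE1_P_C, STAGE1_N_OBSERVE):
        sets.append(
            dict(extension=extension, p_c=p_c, n_observe=n_observe, **STAGE1_FIXED)
        )
    return sets


def pairwise_schedule(
    entries: list[str],
    extension: str,
    param_sets: list[dict] | None = None,
    replicates: int = 2,
    seed: int = 0,
    burn_in: int = 100,
) -> list[ContestSpec]:
    """All pairwise-invasion simulations for a stage-1 contest set.

    Every ordered (defender, invader) pair appears under every
    parameter set, ``replicates`` times; for n entries that is
    n(n-1) ordered contests and
    ``len(param_sets) * 2 * replicates`` simulations per unordered pair.
    """
    if len(entries) < 2:
        raise ValueError("pairwise contests need at least 2 entries")
    if len(set(entries)) != len(entries):
        raise ValueError("duplicate entry names")
    param_sets = stage1_parameter_sets(extension) if param_sets is None else param_sets
    schedule = []
    i = 0
    for defender, invader in itertools.permutations(entries, 2):
        for params in param_sets:
            for rep in range(replicates):
                schedule.append(
                    ContestSpec(
                        defender=defender,
                        invader=invader,
                        extension=params.get("extension", extension),
                        params=tuple(sorted((k, v) for k, v in params.items() if k != "extension")),
                        replicate=rep,
                        burn_in=burn_in,
                        seed=derive_seed(seed, i),
                    )
                )
                i += 1
    return schedule


def n_ordered_contests(n_entries: int) -> int:
    """Ordered defender/invader pairs for a stage-1 round robin."""
    return n_entries * (n_entries - 1)


def _make_cfg(extension: str, params: dict, rounds: int, base: SimulationConfig | None) -> SimulationConfig:
    kwargs = dict(base.model_dump(exclude={"seed"})) if base is not None else {}
    kwargs.pop("n_demes", None)
    kwargs.update(params)
    kwargs["extension"] = extension
    kwargs["rounds"] = rounds
    return SimulationConfig(**kwargs)


def run_invasion_contest(
    spec: ContestSpec,
    registry: dict[str, Strategy],
    rounds: int = 10_000,
    base_cfg: SimulationConfig | None = None,
) -> RunResult:
    """Run one defender-vs-invader invasion simulation.

    The defender starts as a monoculture; mutation switches on after
    the burn-in with the invader as the only mutation target, so the
    invader enters — and can re-enter — through mutation.
    """
    cfg = _make_cfg(spec.extension, spec.param_dict, rounds, base_cfg)
    strategies = {
        spec.defender: registry[spec.defender],
        spec.invader: registry[spec.invader],
    }
    return run_simulation(
        cfg,
        strategies,
        initial=spec.defender,
        seed=spec.seed,
        mutation_start=spec.burn_in,
        mutation_targets=[spec.invader],
    )


def pairwise_stage(
    entries: list[str],
    extension: str,
    registry: dict[str, Strategy],
    seed: int = 0,
    rounds: int = 10_000,
    param_sets: list[dict] | None = None,
    replicates: int = 2,
    base_cfg: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Run the full stage-1 schedule; one row per (simulation, entry).

    Aggregate with :func:`aggregate_scores`.
    """
    schedule = pairwise_schedule(entries, extension, param_sets, replicates, seed)
    rows = []
    for i, spec in enumerate(schedule):
        result = run_invasion_contest(spec, registry, rounds, base_cfg)
        for entry_id, score in result.scores.items():
            rows.append(
                {
                    "contest": i,
                    "defender": spec.defender,
                    "invader": spec.invader,
                    "params": dict(spec.params),
                    "replicate": spec.replicate,
                    "seed": spec.seed,
                    "entry_id": entry_id,
                    "role": "defender" if entry_id == spec.defender else "invader",
                    "score": score,
                }
            )
    return pd.DataFrame(rows)


def aggregate_scores(score_table: pd.DataFrame) -> pd.Series:
    """Mean score per entry across all simulations it took part in."""
    return score_table.groupby("entry_id")["score"].mean().sort_values(ascending=False)


def melee_grid(grid: dict[str, tuple] | None = None) -> list[dict]:
    """The systematic melee parameter grid as a list of dicts."""
    grid = STAGE2_GRID if grid is None else grid
    names = list(grid)
    return [dict(zip(names, values)) for values in itertools.product(*grid.values())]


def draw_melee_params(
    rng: np.random.Generator, spatial: bool = False
) -> dict:
    """One exponential parameter draw for the melee stages.

    Each parameter is drawn from an exponential distribution whose mean
    is the midpoint of its printed systematic range, resampled until it
    falls inside that range; integer parameters are rounded.
    """
    out: dict = {}
    names = ["p_c", "p_copyFail", "n_observe", "r_max"] + (
        ["n_migrate"] if spatial else []
    )
    for name in names:
        lo, hi = MELEE_PARAM_RANGES[name]
        mean = (lo + hi) / 2.0
        while True:
            v = rng.exponential(mean)
            if lo <= v <= hi:
                break
        out[name] = int(round(v)) if name in ("n_observe", "r_max", "n_migrate") else float(v)
    return out


def melee_stage(
    entries: list[str],
    extension: str,
    registry: dict[str, Strategy],
    seed: int = 0,
    rounds: int = 10_000,
    replicates: int = 10,
    grid: dict[str, tuple] | None = None,
    n_random_draws: int = 0,
    resident: str = "innovateOnce",
    base_cfg: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Run a melee: all entries simultaneously invade the resident.

    The population starts as a resident (``innovateOnce``) monoculture
    and every registered entry can arise through mutation from round
    one.  Runs cover the systematic grid (``replicates`` each: 10 in
    the single-extension melee, 5 in the all-extensions melee) plus
    ``n_random_draws`` exponential parameter draws.
    """
    strategies = {e: registry[e] for e in entries}
    if resident not in strategies:
        strategies[resident] = registry.get(resident, innovate_once(resident))

    points = [dict(p) for p in melee_grid(grid) for _ in range(replicates)]
    draw_rng = np.random.default_rng(derive_seed(seed, 1_000_000))
    points += [
        draw_melee_params(draw_rng, spatial=extension in ("spatial", "all"))
        for _ in range(n_random_draws)
    ]

    rows = []
    for i, params in enumerate(points):
        cfg = _make_cfg(extension, params, rounds, base_cfg)
        result = run_simulation(
            cfg,
            strategies,
            initial=resident,
            seed=derive_seed(seed, i),
            mutation_start=0,
            mutation_targets=None,
        )
        for entry_id, score in result.scores.items():
            rows.append(
                {
                    "simulation": i,
                    "params": params,
                    "entry_id": entry_id,
                    "score": score,
                    "total_payoff": result.payoff_by_entry.get(entry_id, 0.0),
                    "max_refinement": result.max_refinement,
                    "refined": result.max_refinement >= cfg.r_max,
                    "seed": derive_seed(seed, i),
                }
            )
    return pd.DataFrame(rows)


def select_top(score_table: pd.DataFrame, k: int) -> list[str]:
    """Stage promotion: top-k entries by mean score.

    Ties are broken by summed EXPLOIT payoff, then lexicographically.
    """
    agg = (
        score_table.groupby("entry_id")
        .agg(score=("score", "mean"), total_payoff=("total_payoff", "sum"))
        .reset_index()
    )
    agg = agg.sort_values(
        by=["score", "total_payoff", "entry_id"], ascending=[False, False, True]
    )
    return agg["entry_id"].head(k).tolist()


def classify_environment(result: RunResult, cfg: SimulationConfig) -> bool:
    """True when the run is a *refined* environment.

    A simulation counts as refined when some agent reached the maximum
    refinement level r_max at any point.
    """
    return result.max_refinement >= cfg.r_max


def refinement_stopping_experiment(
    smart_entries: list[str],
    blind_entry: str,
    stopping_levels: list[float],
    registry: dict[str, Strategy],
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    replicates: int = 50,
    max_rounds: int = 2_000,
    resident: str = "innovateOnce",
) -> pd.DataFrame:
    """Fitness of smart refiners vs the blind copier at stopping levels.

    Melee-style cumulative runs (resident ``innovateOnce``, smart and
    blind entries invading through mutation) halt the first round the
    mean refinement level of the performed (non-forfeited EXPLOIT)
    behaviors exceeds the stopping level.  At that instant the mean
    lifetime payoff of every agent is pooled by class — smart, blind,
    and any surviving resident agents in a class of their own.  Runs
    that never reach the level within ``max_rounds`` are censored.

    Returns a tidy frame: one row per (level, replicate, class) with
    the class mean fitness, plus the stop round and a censoring flag.
    """
    if cfg is None:
        cfg = SimulationConfig(extension="cumulative")
    if not cfg.cumulative_enabled:
        raise ValueError("the stopping experiment requires the cumulative extension")
    entry_set = list(smart_entries) + [blind_entry]
    strategies = {e: registry[e] for e in entry_set}
    strategies[resident] = registry.get(resident, innovate_once(resident))
    smart = set(smart_entries)

    rows = []
    run_index = 0
    for level in stopping_levels:
        for rep in range(replicates):
            def stop(state, outcome, _level=level):
                m = outcome.mean_refinement_performed
                return m == m and m > _level  # NaN-safe comparison

            result = run_simulation(
                cfg,
                strategies,
                initial=resident,
                seed=derive_seed(seed, run_index),
                rounds=max_rounds,
                mutation_start=0,
                mutation_targets=None,
                stop_condition=stop,
            )
            run_index += 1
            censored = result.stopped_round is None
            by_class: dict[str, list[float]] = {"smart": [], "blind": [], "resident": []}
            for entry_id, fitness in result.population_fitness:
                if entry_id in smart:
                    by_class["smart"].append(fitness)
                elif entry_id == blind_entry:
                    by_class["blind"].append(fitness)
                else:
                    by_class["resident"].append(fitness)
            for cls, values in by_class.items():
                rows.append(
                    {
                        "stopping_level": level,
                        "replicate": rep,
                        "class": cls,
                        "mean_fitness": float(np.mean(values)) if values else float("nan"),
                        "n_agents": len(values),
                        "stop_round": result.stopped_round,
                        "censored": censored,
                    }
                )
    return pd.DataFrame(rows)


def stopping_difference(table: pd.DataFrame) -> pd.DataFrame:
    """Per-level mean (smart - blind) fitness from the experiment table.

    Censored runs are excluded; the difference series is the analogue
    of the relative-fitness curve of the refiner-vs-copier comparison.
    """
    ok = table[~table["censored"]]
    wide = (
        ok.pivot_table(
            index=["stopping_level", "replicate"], columns="class", values="mean_fitness"
        )
        .reset_index()
    )
    for cls in ("smart", "blind"):  # a class may have no survivors at stop
        if cls not in wide:
            wide[cls] = float("nan")
    wide["difference"] = wide["smart"] - wide["blind"]
    return (
        wide.groupby("stopping_level")
        .agg(
            smart=("smart", "mean"),
            blind=("blind", "mean"),
            difference=("difference", "mean"),
            n=("difference", "count"),
        )
        .reset_index()
    )
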