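"""The strategy (entry) plugin contract and the shipped reference entries.

An entry is a pair of pure functions:

* ``move(view, rng) -> MoveDecision`` — the per-round decision, seeing
  only the agent's own history, repertoire payoffs, migration record
  and the simulation parameters (:class:`~refinebandit.agents.StrategyView`);
* ``observe_who(model_infos, rng) -> ranked list`` — optional; under
  the model-bias extension it ranks the available models by preference,
  and the first ``n_observe`` become the learning models.

Entries may not persist state between rounds: all randomness comes from
the engine-provided substream and everything else must be recomputed
from the view, so replaying a recorded view sequence reproduces the
decision sequence exactly.

The original 51 submitted tournament entries were never published.  The
two protocol-defined entries (``innovateOnce``, ``observeExploit``) are
implemented faithfully from their one-line definitions; the
``smartRefiner`` family is a documented parametric stand-in for the
"clever" conditional refiners, built to refine only while refinement
looks worthwhile (young agent, low best-known payoff, limited budget).
"""

from __future__ import annotations

import importlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .agents import (
    EXPLOIT,
    INNOVATE,
    OBSERVE,
    REFINE,
    ModelInfo,
    MoveDecision,
    StrategyView,
)

MoveFn = Callable[[StrategyView, np.random.Generator], MoveDecision]
ObserveWhoFn = Callable[[list[ModelInfo], np.random.Generator], list[ModelInfo]]


@dataclass(frozen=True)
class Strategy:
    """A registered entry: name, ``move`` rule, optional ``observe_who``."""

    entry_id: str
    move: MoveFn
    observe_who: ObserveWhoFn | None = None


def _best_known(view: StrategyView) -> int:
    """Behavior with the highest recorded payoff (stable tie-break)."""
    return max(view.repertoire, key=lambda b: (view.repertoire[b], -b))


def innovate_once(entry_id: str = "innovateOnce") -> Strategy:
    """Learn one behavior asocially, then exploit it for life.

    The standard defending entry of the melee stages: INNOVATE on the
    first round, EXPLOIT the (sole) known behavior ever after.
    """

    def move(view: StrategyView, rng: np.random.Generator) -> MoveDecision:
        if not view.repertoire:
            return MoveDecision(INNOVATE)
        return MoveDecision(EXPLOIT, _best_known(view))

    return Strategy(entry_id, move)


def observe_exploit(entry_id: str = "observeExploit") -> Strategy:
    """The blind copier: observe once, then exploit forever.

    Repeats OBSERVE while the repertoire is still empty (a failed or
    model-less observation leaves nothing to exploit), then exploits
    the behavior with the highest recorded payoff for life.
    """

    def move(view: StrategyView, rng: np.random.Generator) -> MoveDecision:
        if not view.repertoire:
            return MoveDecision(OBSERVE)
        return MoveDecision(EXPLOIT, _best_known(view))

    return Strategy(entry_id, move)


def smart_refiner(
    refine_budget: int = 10,
    age_window: int = 30,
    payoff_threshold: float = 60.0,
    entry_id: str | None = None,
) -> Strategy:
    """A conditional refiner: invest in refinement only while it pays.

    Observes while naive, then refines its best-known behavior when all
    of the following hold, and exploits it otherwise:

    * the best recorded payoff is below ``payoff_threshold`` — a payoff
      already above the ceiling of typical basic payoffs signals a
      refined behavior whose remaining increments are small;
    * the agent is younger than ``age_window`` rounds — refining late in
      an (expected 50-round) life leaves too little time to recoup the
      forgone EXPLOIT payoffs;
    * fewer than ``refine_budget`` REFINEs have been played — a cap on
      total investment, set near the number of increments that lifts a
      fresh behavior past the best basic payoff.

    Outside the cumulative extension REFINE is never legal and the
    entry reduces to the blind copier.
    """
    if entry_id is None:
        entry_id = f"smartRefiner_b{refine_budget}_w{age_window}_t{payoff_threshold:g}"

    def move(view: StrategyView, rng: np.random.Generator) -> MoveDecision:
        if not view.repertoire:
            return MoveDecision(OBSERVE)
        best = _best_known(view)
        if (
            view.params.cumulative_enabled
            and refine_budget > 0
            and view.repertoire[best] < payoff_threshold
            and view.rounds_alive <= age_window
            and view.moves.count(REFINE) < refine_budget
        ):
            return MoveDecision(REFINE, best)
        return MoveDecision(EXPLOIT, best)

    return Strategy(entry_id, move)


def payoff_bias_observe_who() -> ObserveWhoFn:
    """Rank models by estimated payoff per round of life, descending.

    The reference model-bias ranking: preference order is
    ``total_payoff_estimate / age_estimate`` (the raw payoff estimate
    when the age estimate is 0), ties broken at random.
    """

    def observe_who(
        models: list[ModelInfo], rng: np.random.Generator
    ) -> list[ModelInfo]:
        def key(m: ModelInfo) -> tuple[float, float]:
            rate = (
                m.total_payoff_estimate / m.age_estimate
                if m.age_estimate > 0
                else float(m.total_payoff_estimate)
            )
            return (rate, rng.random())

        return sorted(models, key=key, reverse=True)

    return observe_who


def payoff_bias_observer(entry_id: str = "payoffBiasObserver") -> Strategy:
    """Blind copier equipped with the payoff-biased model ranking."""
    base = observe_exploit(entry_id)
    return Strategy(entry_id, base.move, payoff_bias_observe_who())


#: Built-in entry factories, by registry name.
BUILTINS: dict[str, Callable[..., Strategy]] = {
    "innovateOnce": innovate_once,
    "observeExploit": observe_exploit,
    "smartRefiner": smart_refiner,
    "payoffBiasObserver": payoff_bias_observer,
}


def get_strategy(name: str, **params) -> Strategy:
    """Instantiate a built-in entry, binding ``name`` as its entry_id."""
    if name in BUILTINS:
        factory = BUILTINS[name]
        if name == "smartRefiner":
            params.setdefault("entry_id", name)
        elif "entry_id" not in params:
            params["entry_id"] = name
        return factory(**params)
    # smartRefiner parameter spellings like "smartRefiner_b10_w30_t60"
    if name.startswith("smartRefiner_"):
        return _parse_smart_refiner(name)
    raise KeyError(f"unknown entry {name!r}; built-ins: {sorted(BUILTINS)}")


def _parse_smart_refiner(name: str) -> Strategy:
    params: dict = {"entry_id": name}
    for token in name.split("_")[1:]:
        if token.startswith("b"):
            params["refine_budget"] = int(token[1:])
        elif token.startswith("w"):
            params["age_window"] = int(token[1:])
        elif token.startswith("t"):
            params["payoff_threshold"] = float(token[1:])
        else:
            raise ValueError(f"cannot parse smartRefiner token {token!r} in {name!r}")
    return smart_refiner(**params)


def build_registry(names: list[str]) -> dict[str, Strategy]:
    """entry_id -> Strategy for a list of built-in names."""
    strategies = [get_strategy(n) for n in names]
    registry = {s.entry_id: s for s in strategies}
    if len(registry) != len(strategies):
        raise ValueError(f"duplicate entry ids in {names}")
    return registry


def load_entry_manifest(path: str | Path) -> dict[str, Strategy]:
    """Load entries from a JSON manifest.

    The manifest maps entry_id to either a built-in name, a
    ``"module:factory"`` import path, or an object
    ``{"factory": ..., "params": {...}}``.  Factories are called with
    ``entry_id`` plus any params and must return a :class:`Strategy`.
    """
    payload = json.loads(Path(path).read_text())
    registry: dict[str, Strategy] = {}
    for entry_id, target in payload.items():
        if isinstance(target, str):
            factory_ref, params = target, {}
        else:
            factory_ref, params = target["factory"], dict(target.get("params", {}))
        if ":" in factory_ref:
            mod_name, fn_name = factory_ref.split(":", 1)
            factory = getattr(importlib.import_module(mod_name), fn_name)
        elif factory_ref in BUILTINS:
            factory = BUILTINS[factory_ref]
        else:
            raise KeyError(f"entry {entry_id!r}: unknown factory {factory_ref!r}")
        params.setdefault("entry_id", entry_id)
        strategy = factory(**params)
        if strategy.entry_id != entry_id:
            strategy = Strategy(entry_id, strategy.move, strategy.observe_who)
        registry[entry_id] = strategy
    return registry
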