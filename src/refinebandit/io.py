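"""Configuration files, run manifests, result serialization and replay.

A :class:`RunManifest` captures everything needed to reproduce a run
bit-for-bit: the full validated configuration, the entry registry
(names plus factory references), the root seed and the named substream
layout, and the software version.  ``replay`` re-executes a manifest
and refuses to run across software versions.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .config import SimulationConfig, preset
from .dynamics import RunResult, run_simulation
from .environment import BanditEnvironment
from .rng import STREAM_NAMES
from .strategies import Strategy, get_strategy

__all__ = [
    "load_config",
    "save_config",
    "RunManifest",
    "build_manifest",
    "save_manifest",
    "load_manifest",
    "replay",
    "results_equal",
    "write_env_csv",
    "write_scores_csv",
]


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a JSON or YAML configuration file.

    Missing fields take the pairwise-stage defaults; unknown keys and
    out-of-range values raise a validation error naming the offending
    fields.  An empty file yields the full default profile.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text) if text.strip() else {}
    if not data:
        return preset("stage1_cumulative")
    return SimulationConfig(**data)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.model_dump()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True))


class RunManifest(BaseModel):
    """Sufficient metadata to reproduce a run exactly."""

    model_config = ConfigDict(extra="forbid")

    kind: str = "simulate"
    version: str = __version__
    created: str = ""
    root_seed: int = 0
    rounds: int | None = None
    config: dict = {}
    entries: dict[str, str] = {}
    initial: str | dict[str, int] = ""
    streams: tuple[str, ...] = STREAM_NAMES
    extra: dict[str, Any] = {}

    def hash(self) -> str:
        payload = self.model_dump()
        payload.pop("created", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def build_manifest(
    cfg: SimulationConfig,
    entry_names: list[str],
    initial: str | dict[str, int],
    seed: int,
    rounds: int | None = None,
    **extra: Any,
) -> RunManifest:
    return RunManifest(
        kind="simulate",
        created=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        root_seed=seed,
        rounds=rounds,
        config=cfg.model_dump(),
        entries={name: name for name in entry_names},
        initial=initial,
        extra=dict(extra),
    )


def save_manifest(manifest: RunManifest, path: str | Path) -> None:
    payload = manifest.model_dump()
    payload["manifest_hash"] = manifest.hash()
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def load_manifest(path: str | Path) -> RunManifest:
    payload = json.loads(Path(path).read_text())
    payload.pop("manifest_hash", None)
    return RunManifest(**payload)


def _registry_from_manifest(manifest: RunManifest) -> dict[str, Strategy]:
    return {eid: get_strategy(ref) for eid, ref in manifest.entries.items()}


def replay(manifest: RunManifest, **record_flags: bool) -> RunResult:
    """Re-execute a manifest; refuses on a software-version mismatch."""
    if manifest.version != __version__:
        raise RuntimeError(
            f"manifest was produced by version {manifest.version}, "
            f"this is {__version__}; refusing to replay"
        )
    cfg = SimulationConfig(**manifest.config)
    return run_simulation(
        cfg,
        _registry_from_manifest(manifest),
        initial=manifest.initial,
        seed=manifest.root_seed,
        rounds=manifest.rounds,
        **record_flags,
    )


def results_equal(a: RunResult, b: RunResult) -> bool:
    """Bit-for-bit equality of scores, trajectory and refinement record."""
    if a.scores != b.scores or a.final_counts != b.final_counts:
        return False
    if a.max_refinement != b.max_refinement or a.rounds_run != b.rounds_run:
        return False
    if (a.composition is None) != (b.composition is None):
        return False
    if a.composition is not None and not a.composition.equals(b.composition):
        return False
    return True


def write_env_csv(
    env: BanditEnvironment, path: str | Path, round_index: int = 0
) -> None:
    """Audit snapshot: columns round, deme, behavior, basic_payoff."""
    rows = [
        (round_index, d, b, int(env.payoffs[d, b]))
        for d in range(env.n_demes)
        for b in range(env.n_behaviors)
    ]
    pd.DataFrame(rows, columns=["round", "deme", "behavior", "basic_payoff"]).to_csv(
        path, index=False
    )


def write_scores_csv(scores: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(scores.items()), columns=["entry_id", "score"]
    ).to_csv(path, index=False)
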