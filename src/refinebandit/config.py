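"""Tournament / simulation configuration.

One :class:`SimulationConfig` object carries every parameter of a run:
the extension in force, the bandit parameters (``p_c``, ``n_observe``,
``p_copyFail``, ``r_max``, ``p_max``, ``n_migrate``), demography
(``death_prob``, ``mutation_prob``), and the scoring window.  Defaults
follow the pairwise-stage profile: 100 agents per deme, 100 behaviors,
10,000 rounds, death probability 0.02 (expected lifespan 50 rounds),
mutation probability 1/50, scores and the mutation shut-off both taken
over the final quarter of the run.
"""

from __future__ import annotations

import math
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

Extension = Literal["none", "cumulative", "model_bias", "spatial", "all"]


class SimulationConfig(BaseModel):
    """All parameters of one evolutionary simulation.

    ``extension="all"`` switches on cumulative culture, model-biased
    copying and spatial structure simultaneously (the final melee
    condition); the single-extension values switch on exactly one.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    extension: Extension = "none"
    n_agents: int = Field(default=100, ge=1, description="agents per deme")
    n_behaviors: int = Field(default=100, ge=1)
    n_demes: int | None = Field(
        default=None, ge=1, description="defaults to 3 under spatial structure, else 1"
    )
    rounds: int = Field(default=10_000, ge=0)

    p_c: float = Field(default=0.01, ge=0.0, le=1.0, description="per-behavior change probability")
    n_observe: int = Field(default=1, ge=1, description="models copied per OBSERVE")
    p_copyFail: float = Field(default=0.05, ge=0.0, le=1.0)
    r_max: int = Field(default=100, ge=1, description="maximum refinement level")
    p_max: float = Field(default=125.0, gt=0.0, description="increment ceiling at r_max")
    n_migrate: int = Field(default=5, ge=0, description="migrants per deme per round (spatial)")

    death_prob: float = Field(default=0.02, ge=0.0, le=1.0)
    mutation_prob: float = Field(default=1 / 50, ge=0.0, le=1.0)
    score_window_fraction: float = Field(default=0.25, gt=0.0, le=1.0)

    seed: int | None = Field(default=None, ge=0)
    strict: bool = Field(
        default=False,
        description="abort on illegal strategy decisions instead of forfeiting the round",
    )

    @model_validator(mode="after")
    def _resolve_demes(self) -> "SimulationConfig":
        if self.n_demes is None:
            object.__setattr__(self, "n_demes", 3 if self.spatial_enabled else 1)
        if self.spatial_enabled and self.n_demes < 2:
            raise ValueError("spatial structure needs n_demes >= 2")
        if not self.spatial_enabled and self.n_demes != 1:
            raise ValueError("multiple demes require the spatial (or all) extension")
        return self

    @property
    def cumulative_enabled(self) -> bool:
        return self.extension in ("cumulative", "all")

    @property
    def model_bias_enabled(self) -> bool:
        return self.extension in ("model_bias", "all")

    @property
    def spatial_enabled(self) -> bool:
        return self.extension in ("spatial", "all")

    @property
    def population_size(self) -> int:
        return self.n_agents * (self.n_demes or 1)

    def score_window_start(self, rounds: int | None = None) -> int:
        """First round index of the scoring window (last quarter by default).

        Mutation is disabled from this round on, and entry frequencies
        are averaged from it to the end of the run.
        """
        rounds = self.rounds if rounds is None else rounds
        return rounds - math.ceil(rounds * self.score_window_fraction)


#: Named configuration presets mirroring the three contest stages.
PRESETS: dict[str, dict] = {
    # Pairwise invasion profile (single extension; p_c mid-value of the
    # stage grid {0.001, 0.01, 0.1}).
    "stage1": dict(rounds=10_000, p_c=0.01, n_observe=1, p_copyFail=0.05, r_max=100),
    "stage1_cumulative": dict(
        extension="cumulative", rounds=10_000, p_c=0.01, n_observe=1, p_copyFail=0.05, r_max=100
    ),
    # Melee profiles; the systematic grids live in refinebandit.tournament.
    "stage2": dict(rounds=10_000, p_c=0.01, n_observe=1, p_copyFail=0.05, r_max=100),
    "stage3": dict(
        extension="all", rounds=10_000, p_c=0.01, n_observe=1, p_copyFail=0.05, r_max=100
    ),
}


def preset(name: str, **overrides) -> SimulationConfig:
    """A :class:`SimulationConfig` from a named preset plus overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SimulationConfig(**params)
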