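"""Cultural-diversity and learning-composition measures.

A population's *behavior* repertoire at a timepoint is the set of
behaviors at least one agent exploited that round; its *knowledge*
repertoire is the union of all living agents' repertoires.  For both,
three measures are computed:

* **amount** — the proportion of the ``S`` possible behaviors present;
* **evenness** — Pielou's index ``J = -sum_i p_i ln p_i / ln S`` of the
  usage (or knowing) distribution, with ``S`` fixed at the number of
  *possible* behaviors, so that J = 1 exactly when all possible
  behaviors occur equally often and J = 0 when a single behavior is
  used by everyone;
* **persistence** — lengths of unbroken runs of rounds during which a
  behavior stays present.  Refinement is not differentiated: a behavior
  counts as the same behavior at any refinement level.

Under spatial structure every measure is computed per deme and then
averaged across demes.  Knowledge evenness uses the proportion of
agents knowing each behavior, the natural analogue of the usage
definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import EXPLOIT

__all__ = [
    "amount",
    "pielou_evenness",
    "run_lengths",
    "persistence",
    "DiversityRecord",
    "diversity_table",
    "block_average",
    "learning_composition",
]


def amount(counts: np.ndarray, n_behaviors: int | None = None) -> float:
    """Proportion of possible behaviors with at least one user/knower.

    ``counts`` is a per-behavior count vector (or a (demes, behaviors)
    matrix, in which case demes are averaged).
    """
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts[None, :]
    n = counts.shape[1] if n_behaviors is None else n_behaviors
    return float(((counts > 0).sum(axis=1) / n).mean())


def pielou_evenness(counts: np.ndarray, S: int) -> float:
    """Pielou's J of a count vector, with the species pool fixed at S.

    ``J = -sum p_i ln p_i / ln S`` over behaviors with positive counts
    (0·ln 0 := 0).  Returns NaN when every count is zero (undefined).
    Invariant to behavior relabeling and to uniform scaling of counts.
    """
    if S < 2:
        raise ValueError("S must be >= 2 for a defined evenness")
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(S))


def _evenness_over_demes(counts: np.ndarray, S: int) -> float:
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts[None, :]
    vals = np.array([pielou_evenness(row, S) for row in counts])
    return float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")


def run_lengths(presence: np.ndarray) -> list[int]:
    """Maximal-run lengths of True values, pooled over rows.

    ``presence`` is a boolean (behaviors, rounds) matrix (a single row
    may be passed as a 1-D vector).  A behavior never present
    contributes no runs.
    """
    presence = np.atleast_2d(np.asarray(presence, dtype=bool))
    runs: list[int] = []
    for row in presence:
        padded = np.concatenate(([0], row.astype(np.int8), [0]))
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        runs.extend((ends - starts).tolist())
    return runs


def persistence(presence: np.ndarray) -> dict[str, float]:
    """Mean / median / max unbroken presence-run length, in rounds."""
    runs = run_lengths(presence)
    if not runs:
        return {"mean": float("nan"), "median": float("nan"), "max": float("nan")}
    arr = np.asarray(runs, dtype=np.float64)
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "max": float(arr.max()),
    }


@dataclass
class DiversityRecord:
    """Amount/evenness at one timepoint, for behavior and knowledge."""

    timepoint: int
    amount_behavior: float
    amount_knowledge: float
    evenness_behavior: float
    evenness_knowledge: float


def diversity_table(
    behavior_counts: np.ndarray,
    knowledge_counts: np.ndarray,
    n_behaviors: int | None = None,
) -> pd.DataFrame:
    """Per-round amount and evenness from (rounds, demes, behaviors) counts."""
    if behavior_counts.shape != knowledge_counts.shape:
        raise ValueError("behavior and knowledge count arrays must align")
    S = behavior_counts.shape[2] if n_behaviors is None else n_behaviors
    rows = []
    for t in range(behavior_counts.shape[0]):
        rows.append(
            DiversityRecord(
                timepoint=t,
                amount_behavior=amount(behavior_counts[t], S),
                amount_knowledge=amount(knowledge_counts[t], S),
                evenness_behavior=_evenness_over_demes(behavior_counts[t], S),
                evenness_knowledge=_evenness_over_demes(knowledge_counts[t], S),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def persistence_summary(counts: np.ndarray) -> dict[str, float]:
    """Persistence summaries from a (rounds, demes, behaviors) count array.

    Runs are found per deme on the behavior-by-round presence matrix,
    pooled over behaviors, summarized per deme, then averaged across
    demes (NaN-aware for demes with no runs at all).
    """
    per_deme = []
    for d in range(counts.shape[1]):
        presence = (counts[:, d, :] > 0).T  # behaviors x rounds
        per_deme.append(persistence(presence))
    out: dict[str, float] = {}
    for key in ("mean", "median", "max"):
        vals = np.asarray([s[key] for s in per_deme])
        out[key] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
    return out


def block_average(series: np.ndarray, block: int = 1000) -> np.ndarray:
    """Average a per-round series in consecutive blocks (time-series cadence).

    The trailing partial block, if any, is averaged over its own length.
    """
    series = np.asarray(series, dtype=np.float64)
    if block < 1:
        raise ValueError("block must be >= 1")
    n_full = len(series) // block
    out = []
    if n_full:
        out.extend(series[: n_full * block].reshape(n_full, block).mean(axis=1))
    if len(series) % block:
        out.append(series[n_full * block :].mean())
    return np.asarray(out)


def learning_composition(move_log: pd.DataFrame) -> pd.DataFrame:
    """Per-entry learning proportions from a move log.

    Learning is any move but EXPLOIT (forfeited rounds are excluded —
    no move was executed).  Columns: ``p_learning`` (learning moves /
    all moves), ``p_social`` (OBSERVE / learning moves), ``p_refine``
    (REFINE / all moves).
    """
    log = move_log[~move_log["forfeited"].astype(bool)]
    rows = []
    for entry_id, grp in log.groupby("entry_id", sort=True):
        n = len(grp)
        learning = (grp["move"] != EXPLOIT).sum()
        social = (grp["move"] == "OBSERVE").sum()
        refine = (grp["move"] == "REFINE").sum()
        rows.append(
            {
                "entry_id": entry_id,
                "n_moves": n,
                "p_learning": learning / n if n else float("nan"),
                "p_social": social / learning if learning else float("nan"),
                "p_refine": refine / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
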