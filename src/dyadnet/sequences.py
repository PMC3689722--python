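"""Backward sequence trees and latency-to-state analysis.

Two complementary views of what surrounds a focal transition:

* :func:`backward_tree` asks *which behavioral paths lead into it*: for
  every occurrence of the focal transition it walks backward through the
  segment's transition sequence, collecting at level k the source state of
  the k-th preceding transition (depth 3 by default).  Walks stop silently
  at the segment start, so level totals can only shrink with depth.  Trees
  are about behavioral order, not time, hence they live strictly within
  spliced segments.

* :func:`latency_to_states` asks *how long until a target state (typically
  harmonious play) is reached afterwards*: the clock starts at the second
  the focal transition completes and runs on real recording seconds —
  'other'-coded gaps count as elapsed, non-target time — until the end of
  the dyad's full stream.  Occurrences after which no target state ever
  appears are censored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .codebook import CodeBook, CombinedState
from .streams import BehavioralStream, Transition, extract_transitions, splice_other

__all__ = [
    "SequenceTree",
    "LatencySummary",
    "LatencyOccurrence",
    "backward_tree",
    "latency_to_states",
    "export_tree",
    "export_latency",
]

DISPLAY_THRESHOLD = 5.0  # percent; rendering cut-off only, counts kept in full


@dataclass
class SequenceTree:
    """Backward distribution of states preceding a focal transition.

    ``levels[k]`` maps each combined state to the number of focal
    occurrences whose k-th preceding transition started there; rates at
    each level are percentages of that level's total.
    """

    focal: Transition
    depth: int
    n_occurrences: int
    levels: dict[int, dict[CombinedState, int]]
    display_threshold: float = DISPLAY_THRESHOLD

    @property
    def is_empty(self) -> bool:
        return self.n_occurrences == 0

    def level_total(self, k: int) -> int:
        return sum(self.levels.get(k, {}).values())

    def rates(self, k: int) -> dict[CombinedState, float]:
        total = self.level_total(k)
        if total == 0:
            return {}
        return {s: 100.0 * c / total for s, c in self.levels[k].items()}

    def displayed(self, k: int) -> dict[CombinedState, float]:
        """Rates at level k passing the display threshold (default >= 5%)."""
        return {s: r for s, r in self.rates(k).items() if r >= self.display_threshold}


def backward_tree(
    streams: Iterable[BehavioralStream],
    codebook: CodeBook,
    focal: Transition,
    depth: int = 3,
) -> SequenceTree:
    """Trace the states preceding every occurrence of a focal transition.

    An occurrence whose backward walk exits its segment stops contributing
    at that level; a focal transition that is never observed yields an
    empty tree (``is_empty``), not an error.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    levels: dict[int, dict[CombinedState, int]] = {k: {} for k in range(1, depth + 1)}
    n_occ = 0
    for stream in streams:
        for segment in splice_other(stream, codebook):
            transitions, _ = extract_transitions(segment)
            for j, tr in enumerate(transitions):
                if tr != focal:
                    continue
                n_occ += 1
                for k in range(1, depth + 1):
                    if j - k < 0:
                        break
                    src = transitions[j - k].source
                    levels[k][src] = levels[k].get(src, 0) + 1
    return SequenceTree(focal=focal, depth=depth, n_occurrences=n_occ, levels=levels)


class LatencyOccurrence(NamedTuple):
    dyad_id: str
    completion_second: int
    latency_seconds: int | None  # None = censored


@dataclass
class LatencySummary:
    """How often and how fast a target state set is reached after a focal transition."""

    focal: Transition
    targets: frozenset[CombinedState]
    n_occurrences: int
    n_reached: int
    n_censored: int
    latencies_seconds: list[int]
    mean_latency: float
    sd_latency: float
    occurrences: list[LatencyOccurrence] = field(default_factory=list)


def latency_to_states(
    streams: Iterable[BehavioralStream],
    codebook: CodeBook,
    focal: Transition,
    targets: Iterable[CombinedState],
) -> LatencySummary:
    """Latency from each focal-transition completion to the first target second.

    The focal transition completes at the first second spent in its target
    state; the latency is the offset to the first subsequent second (that
    second included) whose combined state is in ``targets``, searched to
    the end of the dyad's full stream across splice cuts.  When the focal
    transition's own target state is in ``targets`` the latency is 0.
    Mean and SD (sample) are over reached occurrences only.
    """
    target_set = frozenset(targets)
    if not target_set:
        raise ValueError("targets must be non-empty")
    occurrences: list[LatencyOccurrence] = []
    for stream in streams:
        combined = stream.combined()
        for segment in splice_other(stream, codebook):
            states = segment.combined_states
            for i in range(len(states) - 1):
                if Transition(states[i], states[i + 1]) != focal:
                    continue
                t = segment.start_second + i + 1  # first second in focal's target state
                latency: int | None = None
                for u in range(t, len(combined)):
                    if combined[u] in target_set:
                        latency = u - t
                        break
                occurrences.append(LatencyOccurrence(stream.dyad_id, t, latency))

    reached = [o.latency_seconds for o in occurrences if o.latency_seconds is not None]
    n = len(reached)
    mean = sum(reached) / n if n else float("nan")
    if n >= 2:
        sd = math.sqrt(sum((x - mean) ** 2 for x in reached) / (n - 1))
    else:
        sd = float("nan")
    return LatencySummary(
        focal=focal,
        targets=target_set,
        n_occurrences=len(occurrences),
        n_reached=n,
        n_censored=len(occurrences) - n,
        latencies_seconds=reached,
        mean_latency=mean,
        sd_latency=sd,
        occurrences=occurrences,
    )


# -- exports ---------------------------------------------------------------


def export_tree(tree: SequenceTree, basepath: str | Path) -> list[Path]:
    """Write a tree as nested JSON and a flat TSV (full counts, no cut-off)."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "focal": str(tree.focal),
        "depth": tree.depth,
        "n_occurrences": tree.n_occurrences,
        "display_threshold_percent": tree.display_threshold,
        "levels": {
            str(k): {
                str(s): {"count": c, "rate_percent": tree.rates(k)[s]}
                for s, c in sorted(tree.levels.get(k, {}).items())
            }
            for k in range(1, tree.depth + 1)
        },
    }
    p_json = Path(str(basepath) + ".json")
    p_json.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    rows = [
        {"level": k, "state": str(s), "count": c, "rate_percent": tree.rates(k)[s]}
        for k in range(1, tree.depth + 1)
        for s, c in sorted(tree.levels.get(k, {}).items())
    ]
    p_tsv = Path(str(basepath) + ".tsv")
    pd.DataFrame(rows, columns=["level", "state", "count", "rate_percent"]).to_csv(
        p_tsv, sep="\t", index=False
    )
    return [p_json, p_tsv]


def export_latency(summary: LatencySummary, basepath: str | Path) -> list[Path]:
    """Write per-occurrence latencies (TSV) and the summary (JSON)."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "dyad_id": o.dyad_id,
            "completion_second": o.completion_second,
            "latency_seconds": "censored" if o.latency_seconds is None else o.latency_seconds,
        }
        for o in summary.occurrences
    ]
    p_tsv = Path(str(basepath) + ".tsv")
    pd.DataFrame(rows, columns=["dyad_id", "completion_second", "latency_seconds"]).to_csv(
        p_tsv, sep="\t", index=False
    )
    payload = {
        "focal": str(summary.focal),
        "targets": sorted(str(s) for s in summary.targets),
        "n_occurrences": summary.n_occurrences,
        "n_reached": summary.n_reached,
        "n_censored": summary.n_censored,
        "mean_latency_seconds": summary.mean_latency,
        "sd_latency_seconds": summary.sd_latency,
    }
    p_json = Path(str(basepath) + ".json")
    p_json.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return [p_tsv, p_json]
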