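"""Coded dyad streams: reading, validation, splicing and transition extraction.

A :class:`BehavioralStream` holds one dyad's two parallel per-second code
sequences plus a group label.  Analysis proceeds by removing the seconds
coded 'other' (they carry no specific behavior), splitting what remains
into maximal contiguous :class:`StreamSegment` runs, and emitting a
:class:`Transition` at every consecutive-second pair within a segment whose
combined state changes.  A simultaneous change in both partners' codes is a
single transition; segment boundaries and splice cuts never generate one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .codebook import CodeBook, CombinedState

__all__ = [
    "GROUP_A",
    "GROUP_B",
    "BehavioralStream",
    "StreamSegment",
    "Transition",
    "ValidationFinding",
    "StreamFormatError",
    "StreamIntegrityError",
    "StreamValidationError",
    "read_streams",
    "write_streams",
    "validate_stream",
    "splice_other",
    "extract_transitions",
]

GROUP_A = "full_term"
GROUP_B = "preterm"
_GROUP_ALIASES = {
    "full_term": GROUP_A,
    "fullterm": GROUP_A,
    "full-term": GROUP_A,
    "term": GROUP_A,
    "control": GROUP_A,
    "preterm": GROUP_B,
    "pre_term": GROUP_B,
    "pre-term": GROUP_B,
}


class StreamFormatError(ValueError):
    """The input file does not have the required tabular shape."""


class StreamIntegrityError(ValueError):
    """Seconds are duplicated or non-contiguous within a dyad."""


class StreamValidationError(ValueError):
    """A code outside the code book (or other invariant breach)."""


class Transition(NamedTuple):
    """A directed change between two combined states (source != target)."""

    source: CombinedState
    target: CombinedState

    def __str__(self) -> str:
        return f"{self.source}:{self.target}"

    @classmethod
    def parse(cls, text: str) -> "Transition":
        """Parse ``"1-11:1-12"`` notation (source:target)."""
        left, _, right = text.partition(":")
        return cls(CombinedState.parse(left), CombinedState.parse(right))


@dataclass(frozen=True)
class BehavioralStream:
    """One dyad's paired infant/mother code sequences at 1 s resolution."""

    dyad_id: str
    group: str
    infant_codes: tuple[int, ...]
    mother_codes: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.infant_codes)

    def combined(self) -> list[CombinedState]:
        return [CombinedState(i, m) for i, m in zip(self.infant_codes, self.mother_codes)]


@dataclass(frozen=True)
class StreamSegment:
    """A maximal contiguous run of non-'other' seconds within one stream."""

    dyad_id: str
    group: str
    start_second: int
    combined_states: tuple[CombinedState, ...]

    def __len__(self) -> int:
        return len(self.combined_states)


class ValidationFinding(NamedTuple):
    dyad_id: str
    position: int | None  # second index, or None for whole-stream findings
    rule: str
    detail: str


def _normalize_group(raw: str) -> str:
    key = str(raw).strip().lower()
    if key not in _GROUP_ALIASES:
        raise StreamValidationError(f"unknown group label {raw!r}")
    return _GROUP_ALIASES[key]


REQUIRED_COLUMNS = ("dyad_id", "group", "second", "infant_code", "mother_code")


def read_streams(path: str | Path, codebook: CodeBook) -> list[BehavioralStream]:
    """Read dyad streams from a delimited text file (CSV or TSV, header required).

    Expected columns: ``dyad_id, group, second, infant_code, mother_code``.
    Seconds must be contiguous from 0 per dyad (any constant offset is
    reindexed away); duplicated or gapped seconds raise
    :class:`StreamIntegrityError`, unknown codes :class:`StreamValidationError`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"dyad_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StreamFormatError(f"missing required column(s): {', '.join(missing)}")

    streams: list[BehavioralStream] = []
    for dyad_id, sub in df.groupby("dyad_id", sort=True):
        sub = sub.sort_values("second")
        seconds = sub["second"].to_numpy()
        if len(set(seconds)) != len(seconds):
            dup = int(sub["second"][sub["second"].duplicated()].iloc[0])
            raise StreamIntegrityError(f"dyad {dyad_id}: duplicated second {dup}")
        expected = range(int(seconds[0]), int(seconds[0]) + len(seconds))
        for got, want in zip(seconds, expected):
            if int(got) != want:
                raise StreamIntegrityError(f"dyad {dyad_id}: gap at second {want}")
        groups = set(sub["group"].astype(str))
        if len(groups) != 1:
            raise StreamIntegrityError(f"dyad {dyad_id}: inconsistent group labels {groups}")
        stream = BehavioralStream(
            dyad_id=str(dyad_id),
            group=_normalize_group(groups.pop()),
            infant_codes=tuple(int(c) for c in sub["infant_code"]),
            mother_codes=tuple(int(c) for c in sub["mother_code"]),
        )
        findings = validate_stream(stream, codebook)
        if findings:
            f = findings[0]
            raise StreamValidationError(
                f"dyad {f.dyad_id}: {f.rule} ({f.detail})"
                + (f" at second {f.position}" if f.position is not None else "")
            )
        streams.append(stream)
    return streams


def write_streams(streams: Iterable[BehavioralStream], path: str | Path) -> None:
    """Write streams in the same tabular format ``read_streams`` accepts."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    rows = [
        (s.dyad_id, s.group, t, i, m)
        for s in streams
        for t, (i, m) in enumerate(zip(s.infant_codes, s.mother_codes))
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep=sep, index=False)


def validate_stream(stream: BehavioralStream, codebook: CodeBook) -> list[ValidationFinding]:
    """Check a stream against its invariants; return findings (empty = valid)."""
    findings: list[ValidationFinding] = []
    if len(stream.infant_codes) != len(stream.mother_codes):
        findings.append(
            ValidationFinding(
                stream.dyad_id,
                None,
                "length mismatch",
                f"infant {len(stream.infant_codes)} s vs mother {len(stream.mother_codes)} s",
            )
        )
    if len(stream.infant_codes) == 0:
        findings.append(ValidationFinding(stream.dyad_id, None, "empty stream", "no seconds"))
    for t, code in enumerate(stream.infant_codes):
        if code not in codebook.infant_codes:
            findings.append(
                ValidationFinding(stream.dyad_id, t, "unknown infant code", f"code {code}")
            )
    for t, code in enumerate(stream.mother_codes):
        if code not in codebook.mother_codes:
            findings.append(
                ValidationFinding(stream.dyad_id, t, "unknown mother code", f"code {code}")
            )
    if stream.group not in (GROUP_A, GROUP_B):
        findings.append(
            ValidationFinding(stream.dyad_id, None, "unknown group", repr(stream.group))
        )
    return findings


def splice_other(stream: BehavioralStream, codebook: CodeBook) -> list[StreamSegment]:
    """Remove 'other'-coded seconds and split the rest into contiguous segments.

    Transitions are never counted across a cut: each returned segment is a
    maximal run of consecutive seconds in which neither partner is in an
    'other' state.  A stream consisting entirely of 'other' seconds yields
    an empty list.
    """
    segments: list[StreamSegment] = []
    run: list[CombinedState] = []
    run_start = 0
    for t, state in enumerate(stream.combined()):
        if codebook.is_other(state):
            if run:
                segments.append(
                    StreamSegment(stream.dyad_id, stream.group, run_start, tuple(run))
                )
                run = []
        else:
            if not run:
                run_start = t
            run.append(state)
    if run:
        segments.append(StreamSegment(stream.dyad_id, stream.group, run_start, tuple(run)))
    return segments


def extract_transitions(
    segment: StreamSegment,
) -> tuple[list[Transition], dict[CombinedState, int]]:
    """Emit transitions at every consecutive pair of differing combined states.

    Returns the ordered transition list and a dwell tally mapping each
    combined state to the number of seconds spent in it (every second of
    the segment is counted exactly once).
    """
    if len(segment) == 0:
        raise ValueError("segment must be non-empty")
    transitions: list[Transition] = []
    dwell: dict[CombinedState, int] = {}
    states = segment.combined_states
    dwell[states[0]] = 1
    for prev, cur in zip(states, states[1:]):
        if cur != prev:
            transitions.append(Transition(prev, cur))
        dwell[cur] = dwell.get(cur, 0) + 1
    return transitions, dwell
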