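"""Behavioral code book: the category system for dyadic micro-coding.

Two parallel streams are coded at 1 s resolution: one code per second for
the infant (small integers) and one for the mother (a disjoint integer
range).  A *combined state* is the pair ``(infant_code, mother_code)``
describing both partners during one second; combined states are the node
type of every network in this package.

The default code book ships in ``data/default_codebook.yaml`` and covers
free-play interaction at one year of age: infant codes 1-8 (plays,
explores, obeys, cooperates, defies, neglects, passive, other) and mother
codes 10-20 (other, follows, enriches, forces, commands, directs,
interrupts, passive, neglects, inappropriate, manipulates toy).  The
'other' codes (8 for the infant, 10 for the mother) carry no specific
behavior and are spliced out before transitions are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import yaml

__all__ = ["CombinedState", "CodeBook", "HarmonyClasses"]


class CombinedState(NamedTuple):
    """An (infant code, mother code) pair; one second of joint behavior."""

    infant: int
    mother: int

    def __str__(self) -> str:  # matches the field's "1-11" notation
        return f"{self.infant}-{self.mother}"

    @classmethod
    def parse(cls, text: str) -> "CombinedState":
        """Parse ``"1-11"`` style notation."""
        left, _, right = text.partition("-")
        return cls(int(left), int(right))


@dataclass(frozen=True)
class HarmonyClasses:
    """Interpretive groupings of codes used by the harmony/latency analyses."""

    harmonious_states: frozenset[CombinedState]
    smooth_mother_codes: frozenset[int]
    smooth_infant_codes: frozenset[int]
    disharmonious_infant_codes: frozenset[int]
    disharmonious_mother_codes: frozenset[int]
    neglect_codes: frozenset[int]


@dataclass(frozen=True)
class CodeBook:
    """The category system: code sets, labels, 'other' codes, harmony classes.

    Invariants (checked on construction): infant and mother code sets are
    disjoint, labels are unique, 'other' codes belong to the code sets, and
    every harmony class references only known codes.
    """

    infant_codes: frozenset[int]
    mother_codes: frozenset[int]
    labels: dict[int, str]
    other_codes: frozenset[int]
    harmony: HarmonyClasses = field(repr=False)

    def __post_init__(self) -> None:
        if self.infant_codes & self.mother_codes:
            raise ValueError("infant and mother code sets must be disjoint")
        all_codes = self.infant_codes | self.mother_codes
        if set(self.labels) != all_codes:
            raise ValueError("labels must cover exactly the declared codes")
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("labels must be unique")
        if not self.other_codes <= all_codes:
            raise ValueError("other_codes must be a subset of the code sets")
        h = self.harmony
        for state in h.harmonious_states:
            if state.infant not in self.infant_codes or state.mother not in self.mother_codes:
                raise ValueError(f"harmonious state {state} references unknown codes")
        for codes, domain in [
            (h.smooth_mother_codes, self.mother_codes),
            (h.disharmonious_mother_codes, self.mother_codes),
            (h.smooth_infant_codes, self.infant_codes),
            (h.disharmonious_infant_codes, self.infant_codes),
            (h.neglect_codes, all_codes),
        ]:
            if not codes <= domain:
                raise ValueError("harmony class references unknown codes")

    # -- convenience -------------------------------------------------------

    @property
    def infant_other(self) -> frozenset[int]:
        return self.other_codes & self.infant_codes

    @property
    def mother_other(self) -> frozenset[int]:
        return self.other_codes & self.mother_codes

    def is_other(self, state: CombinedState) -> bool:
        """True when either side of the combined state is an 'other' code."""
        return state.infant in self.other_codes or state.mother in self.other_codes

    def label(self, code: int) -> str:
        return self.labels[code]

    def admissible_states(self) -> list[CombinedState]:
        """All combined states free of 'other' codes, in lexicographic order."""
        return [
            CombinedState(i, m)
            for i in sorted(self.infant_codes - self.other_codes)
            for m in sorted(self.mother_codes - self.other_codes)
        ]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "CodeBook":
        infant = {int(k): str(v) for k, v in raw["infant_codes"].items()}
        mother = {int(k): str(v) for k, v in raw["mother_codes"].items()}
        labels = {}
        for code, name in infant.items():
            labels[code] = f"infant_{name}"
        for code, name in mother.items():
            labels[code] = f"mother_{name}"
        h = raw.get("harmony", {})
        harmony = HarmonyClasses(
            harmonious_states=frozenset(
                CombinedState(int(a), int(b)) for a, b in h.get("harmonious_states", [])
            ),
            smooth_mother_codes=frozenset(h.get("smooth_mother_codes", [])),
            smooth_infant_codes=frozenset(h.get("smooth_infant_codes", [])),
            disharmonious_infant_codes=frozenset(h.get("disharmonious_infant_codes", [])),
            disharmonious_mother_codes=frozenset(h.get("disharmonious_mother_codes", [])),
            neglect_codes=frozenset(h.get("neglect_codes", [])),
        )
        return cls(
            infant_codes=frozenset(infant),
            mother_codes=frozenset(mother),
            labels=labels,
            other_codes=frozenset(raw.get("other_codes", [])),
            harmony=harmony,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeBook":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "CodeBook":
        """The free-play code book shipped with the package."""
        text = (
            resources.files("dyadnet").joinpath("data/default_codebook.yaml").read_text("utf-8")
        )
        return cls.from_dict(yaml.safe_load(text))
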