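"""Experimental design: stimulation sequences and timepoints.

The tolerance protocol cultures macrophages for 24 h with a first (tolerizing)
agonist or medium, washes, then recultures with a second agonist or medium,
sampling 1 h and 4 h after the second stimulation.  With two agonists
(M-triDAP, a NOD1 agonist, and LPS, a TLR4 agonist) plus medium for each slot
and two timepoints, a full experiment comprises 18 conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Stimulus(str, Enum):
    """A stimulation slot: medium only, NOD1 agonist, or TLR4 agonist."""

    NONE = "0"
    M = "M"  # M-triDAP (NOD1 agonist)
    L = "L"  # LPS (TLR4 agonist)


class Timepoint(str, Enum):
    """Hours after the second stimulation at which RNA was sampled."""

    H1 = "1h"
    H4 = "4h"


@dataclass(frozen=True, order=True)
class Condition:
    """One cell of the design: first stimulus, second stimulus, timepoint.

    The string encoding ``"A1->A2@t"`` (e.g. ``"L->0@4h"``) round-trips
    bijectively through :meth:`label` / :meth:`from_label`.
    """

    first: Stimulus
    second: Stimulus
    timepoint: Timepoint

    @property
    def label(self) -> str:
        return f"{self.first.value}->{self.second.value}@{self.timepoint.value}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        try:
            seq, t = label.split("@")
            a1, a2 = seq.split("->")
            return cls(Stimulus(a1), Stimulus(a2), Timepoint(t))
        except ValueError as exc:
            raise ValueError(f"not a valid condition label: {label!r}") from exc

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def all_conditions() -> list[Condition]:
    """The 18 distinct conditions of one experiment (3 x 3 x 2)."""
    return [
        Condition(a1, a2, t)
        for a1 in Stimulus
        for a2 in Stimulus
        for t in Timepoint
    ]
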