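"""Scoring and classification for the 20-item ADL scale.

The scale sums 20 items, each scored in [0, 1], to a total in [0, 20].
The total maps to a three-level disability state:

* total = 20            -> state 1, no ADL disability
* 8 <= total < 20       -> state 2, mild ADL disability
* 0 <= total < 8        -> state 3, severe ADL disability

State codes are ordered by increasing severity (1 < 2 < 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["AdlAssessment", "DisabilityState", "score_total", "classify_state"]

N_ITEMS = 20
MAX_TOTAL = 20.0
MILD_CUTPOINT = 8.0

STATE_LABELS = {1: "no ADL disability", 2: "mild ADL disability", 3: "severe ADL disability"}


@dataclass(frozen=True, order=True)
class DisabilityState:
    """Three-level ADL disability state; higher code = more severe."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in (1, 2, 3):
            raise ValueError(f"state code must be 1, 2 or 3, got {self.code!r}")

    @property
    def label(self) -> str:
        return STATE_LABELS[self.code]


@dataclass(frozen=True)
class AdlAssessment:
    """A full 20-item assessment; ``total`` is the sum of the items."""

    items: tuple[float, ...]

    def __post_init__(self) -> None:
        score_total(self.items)  # validates

    @property
    def total(self) -> float:
        return float(sum(self.items))

    @property
    def state(self) -> DisabilityState:
        return classify_state(self.total)


def score_total(items: Sequence[float]) -> float:
    """Sum 20 item scores (each in [0, 1]) into the total ADL score.

    Raises
    ------
    ValueError
        If there are not exactly 20 items or any item lies outside [0, 1];
        the message names the first offending item index.
    """
    items = list(items)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected exactly {N_ITEMS} items, got {len(items)}")
    for i, v in enumerate(items):
        v = float(v)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"item {i} = {v} outside the allowed range [0, 1]")
    return float(sum(float(v) for v in items))


def classify_state(total: float) -> DisabilityState:
    """Map a total ADL score in [0, 20] to the three-level disability state.

    The cutpoints are exact: 20 is state 1; [8, 20) is state 2; [0, 8) is
    state 3.
    """
    total = float(total)
    if not (0.0 <= total <= MAX_TOTAL):
        raise ValueError(f"total ADL score {total} outside [0, {MAX_TOTAL:g}]")
    if total == MAX_TOTAL:
        return DisabilityState(1)
    if total >= MILD_CUTPOINT:
        return DisabilityState(2)
    return DisabilityState(3)
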