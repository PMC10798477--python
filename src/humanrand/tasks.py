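"""The two behavioural instruments: randomness comparison and complex span.

The comparison task shows 64 pairs of 7-element binary series differing
only in the last element (one pair per length-6 prefix, so the 128
length-7 strings are covered exactly once); a participant's *correctness
index* is the share of pairs where they picked the member with the higher
table complexity.  The complex-span task interleaves letter recall with a
distractor task; its *partial span score* sums letters recalled in the
correct position over all trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .ctm.table import CTMTable
from .errors import ValidationError

Side = Literal["left", "right"]

#: comparison stimuli are 7 elements long: length-6 prefix + final symbol
PAIR_LENGTH = 7

#: heads/tails transcoding used at the I/O boundary (O = heads -> 0)
OR_TO_BINARY = str.maketrans("OR", "01")
BINARY_TO_OR = str.maketrans("01", "OR")

_BINARY = frozenset("01")


@dataclass(frozen=True)
class ComparisonPair:
    """One comparison trial: two series differing only in the last element."""

    prefix: str
    left: str
    right: str
    correct_side: Literal["left", "right", "tie"]
    presentation_order: int

    def __post_init__(self):
        if self.left[:-1] != self.prefix or self.right[:-1] != self.prefix:
            raise ValidationError("pair members must share the prefix")
        if self.left[-1] == self.right[-1]:
            raise ValidationError("pair members must differ in the last element")


@dataclass(frozen=True)
class SpanRecord:
    """One complex-span trial: string length and letters recalled in place."""

    trial_index: int
    string_length: int
    letters_correct: int
    trial_correct: bool

    def __post_init__(self):
        if not 0 <= self.letters_correct <= self.string_length:
            raise ValidationError(
                f"trial {self.trial_index}: letters_correct "
                f"{self.letters_correct} outside 0..{self.string_length}"
            )
        if self.trial_correct and self.letters_correct != self.string_length:
            raise ValidationError(
                f"trial {self.trial_index}: correct trial must recall all letters"
            )


def build_comparison_pairs(
    table: CTMTable, seed: int | np.random.Generator = 0
) -> list[ComparisonPair]:
    """All 64 pairs of 7-element series differing in the last element.

    One pair per length-6 binary prefix.  Which continuation appears on
    which side, and the order of the 64 trials, are randomized under
    ``seed`` -- mirroring the on-screen randomization of the task.  The
    correct side is the member with the strictly greater table complexity
    (equal values give a tie, excluded from scoring downstream).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = []
    for bits in range(1 << (PAIR_LENGTH - 1)):
        prefix = format(bits, f"0{PAIR_LENGTH - 1}b")
        zero, one = prefix + "0", prefix + "1"
        left, right = (zero, one) if rng.random() < 0.5 else (one, zero)
        dv = table.value(left) - table.value(right)
        if dv > 0:
            correct: Literal["left", "right", "tie"] = "left"
        elif dv < 0:
            correct = "right"
        else:
            correct = "tie"
        pairs.append((prefix, left, right, correct))
    order = rng.permutation(len(pairs))
    return [
        ComparisonPair(prefix, left, right, correct, int(pos))
        for (prefix, left, right, correct), pos in zip(pairs, order)
    ]


def correctness_index(
    responses: Sequence[Side | None],
    pairs: Sequence[ComparisonPair],
    count_timeouts_in_denominator: bool = True,
) -> float:
    """Share of non-tie pairs answered with the higher-complexity member.

    ``None`` marks a timeout and counts as incorrect (it stays in the
    denominator by default; pass ``count_timeouts_in_denominator=False``
    to drop unanswered pairs instead).  Tie pairs never enter the
    denominator.
    """
    if len(responses) != len(pairs):
        raise ValidationError(
            f"{len(responses)} responses for {len(pairs)} pairs"
        )
    correct = 0
    scored = 0
    for resp, pair in zip(responses, pairs):
        if resp not in ("left", "right", None):
            raise ValidationError(f"illegal response {resp!r}")
        if pair.correct_side == "tie":
            continue
        if resp is None and not count_timeouts_in_denominator:
            continue
        scored += 1
        if resp == pair.correct_side:
            correct += 1
    if scored == 0:
        raise ValidationError("no scorable pairs")
    return correct / scored


def tie_pairs(pairs: Sequence[ComparisonPair]) -> int:
    return sum(1 for p in pairs if p.correct_side == "tie")


def correctness_from_choices(
    choices: Sequence[str | None],
    table: CTMTable,
    count_timeouts_in_denominator: bool = True,
) -> float:
    """Correctness index from the chosen series themselves.

    Each entry is the 7-element string the participant picked (``None``
    for a timeout); its pair partner is the same string with the last
    element flipped, so no side/order layout is needed to score.  Ties
    are excluded from the denominator as in :func:`correctness_index`.
    """
    correct = 0
    scored = 0
    for s in choices:
        if s is None:
            if count_timeouts_in_denominator:
                scored += 1
            continue
        if len(s) != PAIR_LENGTH or set(s) - _BINARY:
            raise ValidationError(f"illegal chosen series {s!r}")
        partner = s[:-1] + ("1" if s[-1] == "0" else "0")
        dv = table.value(s) - table.value(partner)
        if dv == 0:
            continue
        scored += 1
        if dv > 0:
            correct += 1
    if scored == 0:
        raise ValidationError("no scorable choices")
    return correct / scored


def partial_span_score(
    records: Sequence[SpanRecord], level: Literal["letter", "trial"] = "letter"
) -> int:
    """Total number of correct recalls across all span trials.

    ``level='letter'`` (default) gives partial credit: letters recalled in
    the correct position are summed over every trial, failed ones
    included.  ``level='trial'`` counts only fully correct trials.
    """
    if level == "letter":
        return sum(r.letters_correct for r in records)
    return sum(1 for r in records if r.trial_correct)
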