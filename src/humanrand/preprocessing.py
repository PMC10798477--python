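"""Participant-exclusion rules and analysis-ready cohort assembly.

Both studies applied printed absolute cut-offs, in a fixed order.  Study 1:
series shorter than 103 elements first, then completion times outside 7.5
to 15 minutes.  Study 2: distractor-task accuracy below 85% first, then
partial span scores below 4 or above 10.  Boundary values survive (the
rules say "less than" / "below" / "above").  A percentile mode re-derives
the 10% cuts from the cohort at hand instead, for non-default cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .complexity import BinarySeries
from .errors import ValidationError
from .tasks import SpanRecord

MIN_SERIES_LENGTH = 103
MIN_COMPLETION_MIN = 7.5
MAX_COMPLETION_MIN = 15.0
MIN_OPERATIONS_ACC = 0.85
MIN_SPAN = 4
MAX_SPAN = 10


@dataclass
class ParticipantRecord:
    """Everything recorded for one participant, studies 1 and 2 combined."""

    participant_id: str
    condition: str = "none"
    series: BinarySeries | None = None
    completion_minutes: float | None = None
    comparison_responses: Sequence[str | None] | None = None
    span_records: Sequence[SpanRecord] | None = None
    span_score: int | None = None
    operations_accuracy: float | None = None


@dataclass
class ExclusionReport:
    """Per-rule removal counts (in application order) plus survivor ids."""

    counts: dict[str, int] = field(default_factory=dict)
    survivor_ids: list[str] = field(default_factory=list)
    n_input: int = 0

    def __post_init__(self):
        if sum(self.counts.values()) + len(self.survivor_ids) != self.n_input:
            raise ValidationError("exclusion report does not partition the input")


def _require(record: ParticipantRecord, fields: Sequence[str]) -> None:
    for name in fields:
        if getattr(record, name) is None:
            raise ValidationError(
                f"participant {record.participant_id!r} missing {name}"
            )


def filter_study1(
    records: Sequence[ParticipantRecord],
    percentile_mode: bool = False,
) -> tuple[list[ParticipantRecord], ExclusionReport]:
    """Apply the Study-1 rules: series length, then completion time.

    ``percentile_mode`` recomputes the short-series cut as the cohort's own
    10th length percentile and the fast-completion cut as the 10th time
    percentile (the printed 103-element / 7.5-minute values are how those
    percentiles materialized in the original cohort).
    """
    for r in records:
        _require(r, ["series", "completion_minutes"])
    min_len: float = MIN_SERIES_LENGTH
    min_time: float = MIN_COMPLETION_MIN
    if percentile_mode and records:
        min_len = float(np.percentile([r.series.length for r in records], 10))
        min_time = float(np.percentile([r.completion_minutes for r in records], 10))
    counts = {"short_series": 0, "completion_time": 0}
    survivors = []
    for r in records:
        if r.series.length < min_len:
            counts["short_series"] += 1
        elif not (min_time <= r.completion_minutes <= MAX_COMPLETION_MIN):
            counts["completion_time"] += 1
        else:
            survivors.append(r)
    report = ExclusionReport(
        counts=counts,
        survivor_ids=[r.participant_id for r in survivors],
        n_input=len(records),
    )
    return survivors, report


def filter_study2(
    records: Sequence[ParticipantRecord],
    percentile_mode: bool = False,
) -> tuple[list[ParticipantRecord], ExclusionReport]:
    """Apply the Study-2 rules: distractor accuracy, then span extremes."""
    for r in records:
        _require(r, ["operations_accuracy", "span_score"])
    lo: float = MIN_SPAN
    hi: float = MAX_SPAN
    if percentile_mode and records:
        spans = [
            r.span_score
            for r in records
            if r.operations_accuracy >= MIN_OPERATIONS_ACC
        ]
        if spans:
            lo, hi = np.percentile(spans, [10, 90]).tolist()
    counts = {"operations_accuracy": 0, "span_extreme": 0}
    survivors = []
    for r in records:
        if r.operations_accuracy < MIN_OPERATIONS_ACC:
            counts["operations_accuracy"] += 1
        elif not lo <= r.span_score <= hi:
            counts["span_extreme"] += 1
        else:
            survivors.append(r)
    report = ExclusionReport(
        counts=counts,
        survivor_ids=[r.participant_id for r in survivors],
        n_input=len(records),
    )
    return survivors, report
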