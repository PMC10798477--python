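"""Normalized algorithmic complexity of binary response series.

Two behavioural measures are computed from the Coding-Theorem table:

* ``overall_complexity`` -- the series-level score: the mean normalized
  complexity of its length-11 chunks (the longest length for which table
  values exist with a one-element margin below the table limit);
* ``rolling_complexity`` -- the dynamic score: normalized complexity in a
  moving window of 5 to 9 elements, the putative working-memory span.

Normalization is min-max within a length class: a constant string maps to
0, the most complex string of that length to 1.  ``bdm`` extends the table
beyond 12 elements by block decomposition (sum of block complexities plus
log2 of block multiplicities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .ctm.table import CTMTable
from .errors import DomainError, ValidationError

Condition = Literal["visible", "invisible", "none"]
CONDITIONS = ("visible", "invisible", "none")

#: chunk length used for the overall (series-level) complexity score
OVERALL_CHUNK = 11
#: admissible rolling-window lengths (working-memory span 7 +/- 2)
ROLLING_WINDOWS = range(5, 10)

_BINARY = frozenset("01")


@dataclass(frozen=True)
class BinarySeries:
    """One participant's ordered binary responses."""

    participant_id: str
    condition: Condition
    symbols: str

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )
        if not self.symbols or set(self.symbols) - _BINARY:
            raise ValidationError(
                f"series of {self.participant_id!r} must be a non-empty "
                "string over {0,1}"
            )

    @property
    def length(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class ComplexityProfile:
    """Rolling normalized complexity of one series, plus its overall score.

    ``positions`` holds 0-based indices of window END elements, so the
    profile aligns with the moment each window's last response was typed.
    """

    participant_id: str
    window_w: int
    values: np.ndarray
    positions: np.ndarray
    overall: float | None
    condition: Condition = "none"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=int))
        if self.values.shape != self.positions.shape:
            raise ValidationError("values and positions differ in length")
        if self.values.size and not (
            (self.values >= 0).all() and (self.values <= 1).all()
        ):
            raise ValidationError("normalized values outside [0, 1]")
        if self.overall is not None and not 0 <= self.overall <= 1:
            raise ValidationError("overall complexity outside [0, 1]")


def bdm(s: str, table: CTMTable, block_size: int = 12) -> float:
    """Block-Decomposition complexity of ``s`` in bits.

    The string is cut into consecutive non-overlapping blocks of
    ``block_size``; a trailing remainder shorter than the block is
    discarded.  The estimate sums, over distinct blocks, the block's table
    value plus log2 of its multiplicity.  A string no longer than one block
    reduces to a plain table lookup.
    """
    if not s:
        raise DomainError("empty string")
    if set(s) - _BINARY:
        raise DomainError(f"not a binary string: {s!r}")
    if not 1 <= block_size <= table.lengths[-1]:
        raise DomainError(f"block_size {block_size} outside 1..{table.lengths[-1]}")
    if len(s) <= block_size:
        return table.value(s)
    counts: dict[str, int] = {}
    for i in range(0, len(s) - block_size + 1, block_size):
        block = s[i : i + block_size]
        counts[block] = counts.get(block, 0) + 1
    return sum(table.value(b) + math.log2(m) for b, m in counts.items())


def _min_raw(length: int, block_size: int, table: CTMTable) -> float:
    return bdm("0" * length, table, block_size)


_MAX_RAW_CACHE: dict[tuple[int, int, int], float] = {}


def _max_raw(length: int, block_size: int, table: CTMTable) -> float:
    """Largest BDM value attainable by any string of ``length``.

    With ``m`` blocks available, repeating a block trades a full block
    complexity (many bits) for a log2 multiplicity increment (< 1 bit), so
    the maximum uses the ``m`` most complex distinct blocks, as long as
    there are enough distinct strings -- always the case here (m <= 10 vs
    2^12 candidates).
    """
    if length <= block_size:
        return table.length_max(length)
    key = (id(table), length, block_size)
    if key not in _MAX_RAW_CACHE:
        m = length // block_size
        vals = sorted(
            (table.entries[s] for s in _strings_of_length(block_size)), reverse=True
        )
        if m > len(vals):
            raise DomainError("more blocks than distinct strings; unsupported length")
        _MAX_RAW_CACHE[key] = float(sum(vals[:m]))
    return _MAX_RAW_CACHE[key]


def _strings_of_length(n: int):
    for bits in range(1 << n):
        yield format(bits, f"0{n}b")


def normalize(raw: float, length: int, table: CTMTable, block_size: int = 12) -> float:
    """Min-max normalize a ctm/bdm value within its length class to [0, 1]."""
    lo = _min_raw(length, block_size, table)
    hi = _max_raw(length, block_size, table)
    if hi - lo <= 1e-12:
        raise DomainError(
            f"degenerate length {length}: min and max complexity coincide"
        )
    return min(1.0, max(0.0, (raw - lo) / (hi - lo)))


def normalized_ctm(s: str, table: CTMTable) -> float:
    """Convenience: normalized Coding-Theorem complexity of a short string."""
    return normalize(table.value(s), len(s), table)


def overall_complexity(
    series: BinarySeries,
    table: CTMTable,
    mode: Literal["sliding", "disjoint"] = "sliding",
    chunk: int = OVERALL_CHUNK,
) -> float:
    """Series-level complexity: mean normalized complexity of length-11 chunks.

    ``mode='sliding'`` (default) averages every step-1 window, which loses
    no trailing elements on the 103-120 element series this package
    targets; ``'disjoint'`` averages non-overlapping chunks and discards
    the remainder.
    """
    n = series.length
    if n < chunk:
        raise DomainError(f"series of length {n} shorter than chunk {chunk}")
    step = 1 if mode == "sliding" else chunk
    vals = [
        normalize(table.value(series.symbols[i : i + chunk]), chunk, table)
        for i in range(0, n - chunk + 1, step)
    ]
    return float(np.mean(vals))


def rolling_complexity(
    series: BinarySeries, window_w: int, table: CTMTable
) -> ComplexityProfile:
    """Normalized complexity in a step-1 moving window of 5..9 elements."""
    if window_w not in ROLLING_WINDOWS:
        raise DomainError(f"window_w {window_w} outside 5..9")
    n = series.length
    if n < window_w:
        raise DomainError(f"series of length {n} shorter than window {window_w}")
    values = np.array(
        [
            normalize(table.value(series.symbols[i : i + window_w]), window_w, table)
            for i in range(n - window_w + 1)
        ]
    )
    positions = np.arange(window_w - 1, n)
    overall = overall_complexity(series, table) if n >= OVERALL_CHUNK else None
    return ComplexityProfile(
        participant_id=series.participant_id,
        window_w=window_w,
        values=values,
        positions=positions,
        overall=overall,
        condition=series.condition,
    )
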