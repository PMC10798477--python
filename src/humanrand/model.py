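"""Cognitive model of random-like series generation.

An agent keeps the last ``k`` produced symbols in a working-memory buffer.
At each prompted element it (1) proposes a candidate from its schema of
random outputs -- alternating the previous symbol with probability
``theta``, the empirical alternation bias -- and (2) judges whether
appending the candidate keeps the buffer at least as complex as the
alternative continuation would.  The judgment is executed veridically with
probability ``p_t``, otherwise it degrades to a coin flip.  ``p_t`` decays
exponentially with time-on-task (fatigue) from ``p0`` toward a floor, and
the decay is faster when the produced elements are not displayed
(``invisible`` condition): maintaining them in memory loads the same
attentional resource that executes the judgment.  A rejected candidate is
replaced by the opposite symbol, which is then accepted outright (with a
binary alphabet there is no third option).

Companion simulators produce comparison-task responses (a logistic
psychometric function of the complexity gap) and complex-span runs (letter
recall with logistic accuracy in the string length), so whole studies can
be synthesized end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from .complexity import BinarySeries
from .ctm.table import CTMTable
from .errors import ValidationError
from .tasks import ComparisonPair, SpanRecord

#: omitted stimulus marker returned by :func:`step`
OMITTED = None

SPAN_TRIAL_CAP = 25


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the generation model (one simulated participant)."""

    wm_capacity_k: int = 7
    judgment_accuracy_p0: float = 0.9
    fatigue_rate_lambda: float = 0.01
    fatigue_floor: float = 0.0
    storage_load_kappa: float = 1.0
    schema_alternation_bias_theta: float = 0.65
    condition: Literal["visible", "invisible"] = "invisible"
    series_length: int = 120
    omission_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.wm_capacity_k < 2:
            raise ValidationError("wm_capacity_k must be >= 2")
        for name in (
            "judgment_accuracy_p0",
            "schema_alternation_bias_theta",
            "omission_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.fatigue_floor <= self.judgment_accuracy_p0:
            raise ValidationError("fatigue_floor must lie in [0, p0]")
        if self.fatigue_rate_lambda < 0 or self.storage_load_kappa < 0:
            raise ValidationError("fatigue rate and storage load must be >= 0")
        if self.condition not in ("visible", "invisible"):
            raise ValidationError(f"unknown condition {self.condition!r}")

    @property
    def effective_lambda(self) -> float:
        """Fatigue exponent: storage load inflates it in the invisible condition."""
        return self.fatigue_rate_lambda * (
            1.0 + self.storage_load_kappa * (self.condition == "invisible")
        )


@dataclass
class AgentState:
    """Mutable per-element state of a simulated generator."""

    buffer: str = ""
    t: int = 0
    p_t: float = 1.0


def _accuracy_at(t: int, params: ModelParams) -> float:
    p0 = params.judgment_accuracy_p0
    floor = params.fatigue_floor
    return floor + (p0 - floor) * math.exp(-params.effective_lambda * t)


def initial_state(params: ModelParams) -> AgentState:
    return AgentState(buffer="", t=0, p_t=_accuracy_at(0, params))


def propose_element(
    state: AgentState, params: ModelParams, rng: np.random.Generator
) -> str:
    """Schema proposal: alternate the last symbol with probability theta."""
    if not state.buffer:
        return "01"[rng.integers(2)]
    last = state.buffer[-1]
    alternate = rng.random() < params.schema_alternation_bias_theta
    return ("1" if last == "0" else "0") if alternate else last


def judge_accepts(
    state: AgentState,
    candidate: str,
    params: ModelParams,
    table: CTMTable,
    rng: np.random.Generator,
) -> bool:
    """Complexity judgment on the buffer extended by the candidate.

    Veridical with probability ``p_t``: accept iff the window ending in the
    candidate is at least as complex as the window ending in the opposite
    symbol (both truncated to the last ``k`` symbols; equal lengths, so raw
    table values order exactly like normalized ones).  With probability
    ``1 - p_t`` the judgment degrades to a fair coin flip.
    """
    if not state.buffer:
        return True
    if rng.random() >= state.p_t:
        return bool(rng.integers(2))
    k = params.wm_capacity_k
    other = "1" if candidate == "0" else "0"
    with_cand = (state.buffer + candidate)[-k:]
    with_other = (state.buffer + other)[-k:]
    return table.value(with_cand) >= table.value(with_other)


def step(
    state: AgentState,
    params: ModelParams,
    table: CTMTable,
    rng: np.random.Generator,
) -> tuple[AgentState, str | None]:
    """Advance one prompted element; returns the new state and the emitted
    symbol (or ``None`` when the stimulus was missed)."""
    emitted: str | None
    if params.omission_prob > 0 and rng.random() < params.omission_prob:
        emitted = OMITTED
        buffer = state.buffer
    else:
        candidate = propose_element(state, params, rng)
        if judge_accepts(state, candidate, params, table, rng):
            emitted = candidate
        else:
            emitted = "1" if candidate == "0" else "0"
        buffer = (state.buffer + emitted)[-params.wm_capacity_k:]
    t_next = state.t + 1
    return AgentState(buffer=buffer, t=t_next, p_t=_accuracy_at(t_next, params)), emitted


def generate_series(params: ModelParams, table: CTMTable) -> BinarySeries:
    """Simulate one participant's full response series (seeded, deterministic)."""
    rng = np.random.default_rng(params.seed)
    state = initial_state(params)
    out: list[str] = []
    for _ in range(params.series_length):
        state, emitted = step(state, params, table, rng)
        if emitted is not None:
            out.append(emitted)
    return BinarySeries(
        participant_id=f"sim-{params.seed}",
        condition=params.condition,
        symbols="".join(out),
    )


def simulate_comparison_responses(
    discrimination_alpha: float,
    gain_gamma: float,
    pairs: Sequence[ComparisonPair],
    table: CTMTable,
    rng: np.random.Generator,
) -> list[str]:
    """Choose a side per pair via a logistic function of the complexity gap.

    The correct (more complex) member is chosen with probability
    ``expit(alpha + gamma * delta)`` where ``delta`` is the absolute
    normalized-complexity gap; tie pairs are answered at random.
    """
    if gain_gamma < 0:
        raise ValidationError("gain_gamma must be >= 0")
    responses: list[str] = []
    for pair in pairs:
        n = len(pair.left)
        lo, hi = table.length_min(n), table.length_max(n)
        delta = abs(table.value(pair.left) - table.value(pair.right)) / (hi - lo)
        if pair.correct_side == "tie":
            responses.append("left" if rng.random() < 0.5 else "right")
            continue
        p_correct = expit(discrimination_alpha + gain_gamma * delta)
        if rng.random() < p_correct:
            responses.append(pair.correct_side)
        else:
            responses.append("right" if pair.correct_side == "left" else "left")
    return responses


def simulate_span_test(
    latent_capacity_c: float,
    slope_a: float,
    rng: np.random.Generator,
    max_trials: int = SPAN_TRIAL_CAP,
) -> tuple[list[SpanRecord], bool]:
    """Simulate an adaptive complex-span run.

    Strings start at 2 letters; each letter is recalled in position with
    probability ``expit(a * (c - m))`` for string length ``m``.  A fully
    correct trial lengthens the next string by one; the run ends after two
    consecutive failed trials, or at ``max_trials`` (flagged by the second
    return value).
    """
    if slope_a <= 0:
        raise ValidationError("slope_a must be > 0")
    records: list[SpanRecord] = []
    m = 2
    consecutive_failures = 0
    capped = False
    trial = 0
    while consecutive_failures < 2:
        if trial >= max_trials:
            capped = True
            break
        p_letter = expit(slope_a * (latent_capacity_c - m))
        letters = int((rng.random(m) < p_letter).sum())
        correct = letters == m
        records.append(
            SpanRecord(
                trial_index=trial,
                string_length=m,
                letters_correct=letters,
                trial_correct=correct,
            )
        )
        if correct:
            m += 1
            consecutive_failures = 0
        else:
            consecutive_failures += 1
        trial += 1
    return records, capped
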