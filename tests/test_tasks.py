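"""Comparison-task construction/scoring and span scoring."""

import numpy as np
import pytest

from humanrand.errors import ValidationError
from humanrand.tasks import (
    SpanRecord,
    build_comparison_pairs,
    correctness_from_choices,
    correctness_index,
    partial_span_score,
    tie_pairs,
)


class TestPairConstruction:
    def test_exactly_64_pairs_covering_all_length7_strings(self, table):
        pairs = build_comparison_pairs(table, seed=0)
        assert len(pairs) == 64
        members = {p.left for p in pairs} | {p.right for p in pairs}
        assert len(members) == 128
        assert all(len(m) == 7 for m in members)

    def test_one_pair_per_prefix(self, table):
        pairs = build_comparison_pairs(table, seed=1)
        prefixes = [p.prefix for p in pairs]
        assert len(set(prefixes)) == 64
        for p in pairs:
            assert {p.left, p.right} == {p.prefix + "0", p.prefix + "1"}

    def test_heads_tails_worked_example(self, table):
        # the on-screen pair ORRRROR / ORRRROO transcodes (O->0, R->1) to
        # 0111101 / 0111100: both continuations of the prefix 011110
        pairs = {p.prefix: p for p in build_comparison_pairs(table, seed=2)}
        pair = pairs["011110"]
        assert {pair.left, pair.right} == {"0111100", "0111101"}

    def test_correct_side_tracks_table_order(self, table):
        for pair in build_comparison_pairs(table, seed=3):
            lv, rv = table.value(pair.left), table.value(pair.right)
            if pair.correct_side == "tie":
                assert lv == rv
            else:
                chosen = pair.left if pair.correct_side == "left" else pair.right
                other = pair.right if pair.correct_side == "left" else pair.left
                assert table.value(chosen) > table.value(other)

    def test_side_assignment_varies_with_seed_but_members_do_not(self, table):
        a = build_comparison_pairs(table, seed=0)
        b = build_comparison_pairs(table, seed=9)
        assert any(
            pa.left != pb.left
            for pa, pb in zip(
                sorted(a, key=lambda p: p.prefix),
                sorted(b, key=lambda p: p.prefix),
            )
        )
        assert {p.left for p in a} | {p.right for p in a} == {
            p.left for p in b
        } | {p.right for p in b}


class TestCorrectnessIndex:
    def test_perfect_and_chance_responders(self, table, rng):
        pairs = build_comparison_pairs(table, seed=0)
        perfect = [
            p.correct_side if p.correct_side != "tie" else "left" for p in pairs
        ]
        assert correctness_index(perfect, pairs) == 1.0
        idx = [
            correctness_index(
                [("left", "right")[rng.integers(2)] for _ in pairs], pairs
            )
            for _ in range(50)
        ]
        assert np.mean(idx) == pytest.approx(0.5, abs=0.04)

    def test_index_invariant_to_layout_seed(self, table):
        """Scoring keys on content, not side/order randomization: a
        responder who always picks the higher-complexity member scores 1.0
        under any layout."""
        for seed in (0, 1, 2):
            pairs = build_comparison_pairs(table, seed=seed)
            resp = [
                "left"
                if table.value(p.left) >= table.value(p.right)
                else "right"
                for p in pairs
            ]
            non_tie = [
                (r, p) for r, p in zip(resp, pairs) if p.correct_side != "tie"
            ]
            assert (
                correctness_index(resp, pairs)
                == sum(r == p.correct_side for r, p in non_tie) / len(non_tie)
                == 1.0
            )

    def test_timeouts_count_as_incorrect_by_default(self, table):
        pairs = build_comparison_pairs(table, seed=0)
        resp = [None] * len(pairs)
        assert correctness_index(resp, pairs) == 0.0
        with pytest.raises(ValidationError):
            correctness_index(resp, pairs, count_timeouts_in_denominator=False)

    def test_tie_count_is_a_table_constant(self, table):
        assert tie_pairs(build_comparison_pairs(table, seed=0)) == TIE_COUNT

    def test_choice_scoring_agrees_with_pair_scoring(self, table, rng):
        """Scoring from the chosen strings alone must match the pair-based
        index: the pair is recoverable from any member by flipping its
        last element."""
        pairs = build_comparison_pairs(table, seed=4)
        sides = [
            ("left", "right")[rng.integers(2)] if rng.random() > 0.1 else None
            for _ in pairs
        ]
        chosen = [
            None if s is None else (p.left if s == "left" else p.right)
            for s, p in zip(sides, pairs)
        ]
        assert correctness_from_choices(chosen, table) == pytest.approx(
            correctness_index(sides, pairs)
        )

    def test_choice_scoring_validates_input(self, table):
        with pytest.raises(ValidationError):
            correctness_from_choices(["01"], table)
        with pytest.raises(ValidationError):
            correctness_from_choices(
                [None], table, count_timeouts_in_denominator=False
            )

    def test_response_count_mismatch(self, table):
        pairs = build_comparison_pairs(table, seed=0)
        with pytest.raises(ValidationError):
            correctness_index(["left"], pairs)


#: number of last-element complexity ties among the 64 pairs, a regression
#: constant of the packaged table (frozen from a table scan)
TIE_COUNT = 0


class TestPartialSpan:
    def test_letter_level_sum(self):
        records = [
            SpanRecord(0, 2, 2, True),
            SpanRecord(1, 3, 3, True),
            SpanRecord(2, 4, 4, True),
            SpanRecord(3, 5, 0, False),
            SpanRecord(4, 5, 0, False),
        ]
        assert partial_span_score(records) == 9
        assert partial_span_score(records, level="trial") == 3

    def test_empty_is_zero(self):
        assert partial_span_score([]) == 0

    def test_monotone_under_append(self, rng):
        records = []
        prev = 0
        for i in range(10):
            m = int(rng.integers(2, 8))
            lc = int(rng.integers(0, m + 1))
            records.append(SpanRecord(i, m, lc, lc == m))
            score = partial_span_score(records)
            assert score >= prev
            prev = score

    def test_record_validation(self):
        with pytest.raises(ValidationError):
            SpanRecord(0, 3, 4, False)
        with pytest.raises(ValidationError):
            SpanRecord(0, 3, 2, True)
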