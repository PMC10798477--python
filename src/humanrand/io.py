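"""CSV/JSON schemas of the pipeline.

All positions are 0-based; rolling-profile positions index the window END
element.  Symbols may be written as 0/1 or as the task's O/R letters
(O = heads = 0 by convention); transcoding happens only here, at the I/O
boundary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .complexity import BinarySeries, ComplexityProfile
from .errors import ValidationError
from .preprocessing import ExclusionReport
from .tasks import BINARY_TO_OR, OR_TO_BINARY, ComparisonPair, SpanRecord

SERIES_COLUMNS = ["participant_id", "condition", "position", "symbol"]


def write_series_csv(
    series: Sequence[BinarySeries], path: str | Path, alphabet: str = "01"
) -> None:
    rows = []
    for s in series:
        symbols = s.symbols if alphabet == "01" else s.symbols.translate(BINARY_TO_OR)
        rows.extend(
            {
                "participant_id": s.participant_id,
                "condition": s.condition,
                "position": i,
                "symbol": sym,
            }
            for i, sym in enumerate(symbols)
        )
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> list[BinarySeries]:
    df = pd.read_csv(path, dtype={"symbol": str, "participant_id": str})
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (pid, cond), grp in df.groupby(["participant_id", "condition"], sort=True):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(len(pos))):
            raise ValidationError(
                f"{path}: positions of {pid!r} are not consecutive from 0"
            )
        symbols = "".join(grp["symbol"]).translate(OR_TO_BINARY)
        out.append(BinarySeries(str(pid), str(cond), symbols))
    return out


def write_profiles_csv(
    profiles: Sequence[ComplexityProfile], path: str | Path
) -> None:
    rows = []
    for p in profiles:
        rows.extend(
            {
                "participant_id": p.participant_id,
                "condition": p.condition,
                "window_w": p.window_w,
                "position": int(t),
                "normalized_complexity": float(v),
            }
            for t, v in zip(p.positions, p.values)
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> list[ComplexityProfile]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    out = []
    for (pid, cond, w), grp in df.groupby(
        ["participant_id", "condition", "window_w"], sort=True
    ):
        grp = grp.sort_values("position")
        out.append(
            ComplexityProfile(
                participant_id=str(pid),
                window_w=int(w),
                values=grp["normalized_complexity"].to_numpy(),
                positions=grp["position"].to_numpy(),
                overall=None,
                condition=str(cond),
            )
        )
    return out


def write_summary_csv(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pairs_csv(pairs: Sequence[ComparisonPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "prefix": p.prefix,
                "left": p.left,
                "right": p.right,
                "correct_side": p.correct_side,
                "tie_flag": p.correct_side == "tie",
                "presentation_order": p.presentation_order,
            }
            for p in pairs
        ]
    ).to_csv(path, index=False)


def write_responses_csv(
    rows: Sequence[tuple[str, str, str | None]], path: str | Path
) -> None:
    """Rows are (participant_id, pair_prefix, chosen_side | None)."""
    pd.DataFrame(
        [
            {"participant_id": pid, "pair_prefix": prefix, "chosen_side": side}
            for pid, prefix, side in rows
        ]
    ).to_csv(path, index=False)


def write_span_csv(
    rows: Sequence[tuple[str, SpanRecord]], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": pid,
                "trial_index": r.trial_index,
                "string_length": r.string_length,
                "letters_correct": r.letters_correct,
                "trial_correct": r.trial_correct,
            }
            for pid, r in rows
        ]
    ).to_csv(path, index=False)


def read_span_csv(path: str | Path) -> dict[str, list[SpanRecord]]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    out: dict[str, list[SpanRecord]] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        out[str(pid)] = [
            SpanRecord(
                trial_index=int(r.trial_index),
                string_length=int(r.string_length),
                letters_correct=int(r.letters_correct),
                trial_correct=bool(r.trial_correct),
            )
            for r in grp.sort_values("trial_index").itertuples()
        ]
    return out


def write_exclusion_report(report: ExclusionReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "n_input": report.n_input,
                "removed": report.counts,
                "survivors": report.survivor_ids,
            },
            indent=1,
        )
        + "\n"
    )


def result_to_json(result, path: str | Path) -> None:
    """Serialize any result dataclass (tuples/arrays coerced) to JSON."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(
        json.dumps(dataclasses.asdict(result), default=default, indent=1) + "\n"
    )
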