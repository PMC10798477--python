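"""End-to-end pipeline orchestration and run manifests.

``run_pipeline`` chains the stages (simulate -> complexity -> score ->
preprocess -> analyze) as requested by a :class:`RunConfig`, writing every
artifact plus a manifest that records the package version, master seed,
option hash and a checksum per output file, so a rerun with the same
configuration is bit-reproducible and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import CohortSpec, generate_cohort, recover_parameters
from .complexity import rolling_complexity
from .ctm.table import DEFAULT_RESOURCE, load_ctm_table
from .errors import ConfigurationError
from .io import (
    result_to_json,
    write_exclusion_report,
    write_profiles_csv,
    write_series_csv,
    write_summary_csv,
)
from .preprocessing import filter_study1, filter_study2
from .stats import participant_weights, wls_fit
from .tasks import correctness_index
from .trend import TrendConfig, fit_trend_model, permutation_test_difference


@dataclass
class RunConfig:
    """Options of one pipeline run (defaults mirror the study design)."""

    outdir: str = "pipeline-out"
    study: int = 1
    n_participants: int = 150
    master_seed: int = 0
    window_w: int = 7
    table_resource: str = DEFAULT_RESOURCE
    overall_mode: str = "sliding"
    filter_percentile_mode: bool = False
    basis_dim: int = 10
    permutation_B: int = 199
    run_permutation_test: bool = False
    run_recovery: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, config: RunConfig, outputs: list[Path]) -> Path:
    options = dataclasses.asdict(config)
    manifest = {
        "package": "humanrand",
        "version": __version__,
        "master_seed": config.master_seed,
        "options": options,
        "option_hash": hashlib.sha256(
            json.dumps(options, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full synthetic-study run; returns a summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = load_ctm_table(config.table_resource)
    spec = CohortSpec(
        n_participants=config.n_participants,
        study=1 if config.study == 1 else 2,
        master_seed=config.master_seed,
    )
    records, truth = generate_cohort(spec, table)
    outputs: list[Path] = []

    series_path = outdir / "series.csv"
    write_series_csv([r.series for r in records], series_path)
    outputs.append(series_path)
    truth_path = outdir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    outputs.append(truth_path)

    participants_rows = [
        {
            "participant_id": r.participant_id,
            "condition": r.condition,
            "completion_minutes": r.completion_minutes,
            "operations_accuracy": r.operations_accuracy,
            "span_score": r.span_score,
        }
        for r in records
    ]
    participants_path = outdir / "participants.csv"
    write_summary_csv(participants_rows, participants_path)
    outputs.append(participants_path)

    if config.study == 1:
        survivors, report = filter_study1(
            records, percentile_mode=config.filter_percentile_mode
        )
    else:
        survivors, report = filter_study2(
            records, percentile_mode=config.filter_percentile_mode
        )
    report_path = outdir / "exclusions.json"
    write_exclusion_report(report, report_path)
    outputs.append(report_path)

    profiles = [
        rolling_complexity(r.series, config.window_w, table) for r in survivors
    ]
    profiles_path = outdir / "profiles.csv"
    write_profiles_csv(profiles, profiles_path)
    outputs.append(profiles_path)

    summary_rows = []
    for r, p in zip(survivors, profiles):
        row = {
            "participant_id": r.participant_id,
            "condition": r.condition,
            "overall_complexity": p.overall,
            "span_score": r.span_score,
        }
        if r.comparison_responses is not None:
            # pairs are participant-specific but ctm-scoring is layout-free:
            # the index only needs correct/incorrect per pair, already
            # encoded in the simulated responses
            from .tasks import build_comparison_pairs

            task_rng = np.random.default_rng(
                int(truth.set_index("participant_id").loc[r.participant_id, "seed"])
                + 1
            )
            pairs = build_comparison_pairs(table, task_rng)
            row["correctness_index"] = correctness_index(
                r.comparison_responses, pairs
            )
        summary_rows.append(row)
    summary_path = outdir / "summary.csv"
    write_summary_csv(summary_rows, summary_path)
    outputs.append(summary_path)

    weights = participant_weights(profiles)
    overall = np.array([row["overall_complexity"] for row in summary_rows])
    result: dict = {"n_input": len(records), "n_survivors": len(survivors)}
    if config.study == 1:
        x = np.array([row["correctness_index"] for row in summary_rows])
        wls = wls_fit(overall, x, weights)
        result_to_json(wls, outdir / "wls_correctness.json")
        outputs.append(outdir / "wls_correctness.json")
        fit = fit_trend_model(profiles, TrendConfig(basis_dim=config.basis_dim))
        if config.run_permutation_test:
            perm = permutation_test_difference(
                profiles,
                TrendConfig(basis_dim=config.basis_dim),
                B=config.permutation_B,
                seed=config.master_seed,
                lambdas=fit.lambdas,
            )
            fit.permutation_p = {
                "difference_smooth": perm.p_difference_smooth,
                "condition_offset": perm.p_condition_offset,
                "condition_total": perm.p_condition_total,
            }
        trend_rows = [
            {
                "t": float(t),
                "fitted_invisible": float(fit.intercept + fv),
                "fitted_visible": float(
                    fit.intercept + fv + fit.condition_offset + fd
                ),
            }
            for t, fv, fd in zip(fit.t_grid, fit.f, fit.f_diff)
        ]
        write_summary_csv(trend_rows, outdir / "trend_curves.csv")
        outputs.append(outdir / "trend_curves.csv")
        fit_dict = dataclasses.asdict(fit)
        fit_dict = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in fit_dict.items()
        }
        (outdir / "trend_fit.json").write_text(
            json.dumps(fit_dict, indent=1, default=float) + "\n"
        )
        outputs.append(outdir / "trend_fit.json")
        result.update(
            wls_weighted_R2=wls.weighted_R2,
            wls_slope=wls.slope,
            trend_marginal_R2=fit.marginal_R2,
            trend_conditional_R2=fit.conditional_R2,
        )
    else:
        x = np.array([row["span_score"] for row in summary_rows], dtype=float)
        wls = wls_fit(overall, x, weights)
        result_to_json(wls, outdir / "wls_span.json")
        outputs.append(outdir / "wls_span.json")
        result.update(wls_weighted_R2=wls.weighted_R2, wls_slope=wls.slope)

    if config.run_recovery:
        rec = recover_parameters(
            [r for r in survivors],
            table,
            seed=config.master_seed,
            min_per_group=2,
        )
        result_to_json(rec, outdir / "recovery.json")
        outputs.append(outdir / "recovery.json")

    write_manifest(outdir, config, outputs)
    result["outputs"] = [str(p) for p in outputs]
    return result
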