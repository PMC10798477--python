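"""Synthetic cohorts: determinism, filter exercise, latent structure."""

import numpy as np
import pytest
from scipy import stats as sps

from humanrand.cohort import (
    CohortSpec,
    generate_cohort,
    recover_parameters,
)
from humanrand.complexity import overall_complexity, rolling_complexity
from humanrand.errors import ValidationError
from humanrand.io import write_series_csv
from humanrand.preprocessing import filter_study1, filter_study2
from humanrand.stats import participant_weights, wls_fit


@pytest.fixture(scope="module")
def small_cohort(table):
    spec = CohortSpec(n_participants=40, master_seed=7)
    return generate_cohort(spec, table)


class TestGeneration:
    def test_deterministic_under_master_seed(self, table, tmp_path):
        spec = CohortSpec(n_participants=10, master_seed=3)
        rec_a, truth_a = generate_cohort(spec, table)
        rec_b, truth_b = generate_cohort(spec, table)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_series_csv([r.series for r in rec_a], pa)
        write_series_csv([r.series for r in rec_b], pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert truth_a.equals(truth_b)

    def test_condition_alternates_with_id(self, small_cohort):
        records, _ = small_cohort
        assert records[0].condition == "visible"
        assert records[1].condition == "invisible"
        conds = {r.condition for r in records}
        assert conds == {"visible", "invisible"}

    def test_study2_is_all_visible(self, table):
        records, _ = generate_cohort(
            CohortSpec(n_participants=6, study=2, master_seed=1), table
        )
        assert {r.condition for r in records} == {"visible"}

    def test_ground_truth_joins_on_id(self, small_cohort):
        records, truth = small_cohort
        assert set(truth.participant_id) == {r.participant_id for r in records}
        assert {"k", "p0", "lambda", "theta", "alpha", "c", "z"} <= set(
            truth.columns
        )

    def test_series_lengths_plausible(self, small_cohort):
        records, _ = small_cohort
        lengths = [r.series.length for r in records]
        assert all(60 <= n <= 120 for n in lengths)
        assert np.median(lengths) >= 110

    def test_spec_validation(self):
        with pytest.raises(ValidationError):
            CohortSpec(n_participants=2)
        with pytest.raises(ValidationError):
            CohortSpec(rho=1.5)


class TestFilterExercise:
    def test_exclusion_rates_near_configured(self, table):
        """Study-1 filters should remove participants at roughly the rates
        the generator is configured to produce (checked over seeds)."""
        short, time_out, n_tot = 0, 0, 0
        for seed in range(6):
            records, _ = generate_cohort(
                CohortSpec(n_participants=50, master_seed=seed), table
            )
            _, report = filter_study1(records)
            short += report.counts["short_series"]
            time_out += report.counts["completion_time"]
            n_tot += report.n_input
        spec = CohortSpec()
        assert short / n_tot == pytest.approx(spec.short_series_rate, abs=0.05)
        assert time_out / n_tot == pytest.approx(
            spec.completion_outlier_rate, abs=0.05
        )

    def test_study2_filters_have_work(self, table):
        records, _ = generate_cohort(
            CohortSpec(n_participants=80, study=2, master_seed=2), table
        )
        survivors, report = filter_study2(records)
        assert 0 < sum(report.counts.values()) < len(records) // 2
        assert len(survivors) >= 40


@pytest.fixture(scope="module")
def latent_cohort(table):
    spec = CohortSpec(n_participants=120, master_seed=7)
    return generate_cohort(spec, table)


class TestLatentStructure:
    def test_span_slope_increases_with_rho(self, table):
        """Uncoupling the latent ability (rho = 0) must flatten the
        span-complexity regression relative to the coupled default."""
        slopes = {}
        for rho in (0.0, 0.8):
            vals = []
            for seed in (0, 1, 2):
                records, _ = generate_cohort(
                    CohortSpec(
                        n_participants=80, study=2, rho=rho, master_seed=seed
                    ),
                    table,
                )
                profiles = [
                    rolling_complexity(r.series, 7, table) for r in records
                ]
                y = [p.overall for p in profiles]
                x = [float(r.span_score) for r in records]
                w = participant_weights(profiles)
                vals.append(wls_fit(y, x, w).slope)
            slopes[rho] = np.mean(vals)
        assert slopes[0.8] > slopes[0.0]

    def test_default_cohort_effect_size_in_target_band(self, table):
        """A default 150-participant cohort run through the full pipeline
        yields a weighted R2 for the correctness-complexity regression in
        the band around the order of magnitude the analyses are designed
        for (a few to ~15 percent)."""
        from humanrand.tasks import build_comparison_pairs, correctness_index

        records, truth = generate_cohort(
            CohortSpec(n_participants=150, master_seed=0), table
        )
        survivors, _ = filter_study1(records)
        profiles = [rolling_complexity(r.series, 7, table) for r in survivors]
        y = [p.overall for p in profiles]
        idx = truth.set_index("participant_id")
        x = [
            correctness_index(
                r.comparison_responses,
                build_comparison_pairs(
                    table,
                    np.random.default_rng(
                        int(idx.loc[r.participant_id, "seed"]) + 1
                    ),
                ),
            )
            for r in survivors
        ]
        res = wls_fit(y, x, participant_weights(profiles))
        assert res.slope > 0
        assert 0.03 <= res.weighted_R2 <= 0.18

    def test_ability_propagates_to_complexity(self, table, latent_cohort):
        """The latent ability reaches series complexity through the
        judgment-accuracy and fatigue channels."""
        records, truth = latent_cohort
        overall = [
            overall_complexity(r.series, table)
            for r in records
            if r.series.length >= 11
        ]
        rho = sps.spearmanr(truth["z"], overall)
        assert rho.statistic > 0
        assert rho.pvalue < 0.01


class TestRecovery:
    def test_smoke_recovery_on_fixed_k(self, table):
        spec = CohortSpec(
            n_participants=30,
            k_support=(7,),
            lambda_gamma=(1e-9, 1.0),  # effectively lambda = 0
            short_series_rate=0.0,
            master_seed=5,
        )
        records, _ = generate_cohort(spec, table)
        res = recover_parameters(records, table, min_per_group=10, seed=0)
        for cond in res.k_hat:
            assert res.k_hat[cond] in (5, 6, 7, 8, 9)
            assert res.lambda_hat[cond] <= 0.005
        assert res.n_excluded_constant == 0

    def test_constant_series_excluded_not_fatal(self, table):
        from humanrand.complexity import BinarySeries
        from humanrand.preprocessing import ParticipantRecord

        spec = CohortSpec(n_participants=24, master_seed=9)
        records, _ = generate_cohort(spec, table)
        records.append(
            ParticipantRecord(
                participant_id="flat",
                condition="visible",
                series=BinarySeries("flat", "visible", "0" * 120),
            )
        )
        res = recover_parameters(records, table, min_per_group=5, seed=1)
        assert res.n_excluded_constant == 1
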