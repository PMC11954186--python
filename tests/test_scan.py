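import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtseason import (
    DeathSpec,
    SimulationConfig,
    ScanSettings,
    composite_disease_phenotypes,
    fit_interaction,
    generate_cohort,
    incident_disease_exposure,
    lambda_gc,
    mortality_interaction,
    run_scan,
    summarize_interaction,
    zscore_correlations,
)

from .conftest import make_marker_cohort


class TestFitInteraction:
    def test_amplitude_drop_construction(self):
        # groups with amplitudes 0.5 vs 0.3 at common phase 0
        cohort, _ = make_marker_cohort(amplitude=0.5, amplitude_change=-0.2)
        fit = fit_interaction(cohort.outcome, cohort.month, cohort.m)
        assert fit.beta_mcos == pytest.approx(-0.2, abs=1e-9)
        assert fit.beta_msin == pytest.approx(0.0, abs=1e-9)

    def test_phase_shift_construction(self):
        cohort, _ = make_marker_cohort(
            amplitude=0.5, acrophase_shift=np.pi / 6
        )
        fit = fit_interaction(cohort.outcome, cohort.month, cohort.m)
        assert fit.beta_mcos == pytest.approx(0.5 * np.cos(np.pi / 6) - 0.5, abs=1e-9)
        assert fit.beta_msin == pytest.approx(0.25, abs=1e-9)

    def test_constant_marker_errors(self, rng):
        months = rng.integers(1, 13, size=100)
        with pytest.raises(ValueError, match="constant"):
            fit_interaction(rng.normal(size=100), months, np.ones(100))

    def test_missing_marker_rows_dropped(self, rng):
        months = rng.integers(1, 13, size=200)
        y = rng.normal(size=200)
        marker = rng.binomial(1, 0.5, size=200).astype(float)
        marker[:50] = np.nan
        fit = fit_interaction(y, months, marker)
        assert fit.n_used == 150
        assert fit.n_dropped == 50

    def test_mutual_adjust_main_effects_only(self, rng):
        months = rng.integers(1, 13, size=500)
        y = rng.normal(size=500)
        marker = rng.normal(size=500)
        other = pd.DataFrame({"o": rng.normal(size=500)})
        fit = fit_interaction(y, months, marker, mutual_adjust=other)
        assert "o" in fit.params.index
        assert "o:cosw" not in fit.params.index

    def test_null_zscores_standard_normal(self, rng):
        zs = {"amplitude": [], "acrophase": [], "displacement": []}
        for _ in range(400):
            months = rng.integers(1, 13, size=400)
            angle = 2 * np.pi * (months - 1) / 12
            y = 0.5 * np.cos(angle) + rng.normal(size=400)
            marker = rng.binomial(1, 0.5, size=400).astype(float)
            fit = fit_interaction(y, months, marker)
            s = summarize_interaction(fit, reference_amplitude=0.5)
            zs["amplitude"].append(s.delta_amplitude_pct.t_score)
            zs["acrophase"].append(s.delta_acrophase_months.t_score)
            zs["displacement"].append(s.displacement.t_score)
        for stream, vals in zs.items():
            assert abs(np.mean(vals)) < 0.1, stream
            assert 0.85 < np.std(vals) < 1.15, stream


class TestSummarize:
    def test_no_interaction_identity(self):
        cohort, _ = make_marker_cohort(amplitude=0.5, displacement=0.3)
        fit = fit_interaction(cohort.outcome, cohort.month, cohort.m)
        s = summarize_interaction(fit)
        assert s.delta_amplitude_pct.estimate == pytest.approx(0.0, abs=1e-6)
        assert s.delta_acrophase_months.estimate == pytest.approx(0.0, abs=1e-6)
        assert s.displacement.estimate == pytest.approx(0.3, abs=1e-9)

    def test_phase_shift_is_one_month(self):
        cohort, _ = make_marker_cohort(amplitude=0.5, acrophase_shift=np.pi / 6)
        fit = fit_interaction(cohort.outcome, cohort.month, cohort.m)
        s = summarize_interaction(fit)
        assert s.delta_amplitude_pct.estimate == pytest.approx(0.0, abs=1e-6)
        assert s.delta_acrophase_months.estimate == pytest.approx(1.0, abs=1e-8)
        assert s.delta_acrophase_pct_month == pytest.approx(100.0, abs=1e-6)

    def test_amplitude_drop_is_minus_forty_pct(self):
        cohort, _ = make_marker_cohort(amplitude=0.5, amplitude_change=-0.2)
        fit = fit_interaction(cohort.outcome, cohort.month, cohort.m)
        s = summarize_interaction(fit, reference_amplitude=0.5)
        assert s.delta_amplitude_pct.estimate == pytest.approx(-40.0, abs=1e-6)

    def test_definitions_agree_to_first_order(self):
        # shrinking-effect sequence: exact vs linearised definitions converge
        rel_diffs = []
        for i, eff in enumerate([0.2, 0.1, 0.05, 0.025, 0.0125]):
            cohort, _ = make_marker_cohort(
                seed=100 + i, amplitude=0.5, amplitude_change=-eff,
                acrophase_shift=eff,
            )
            fit = fit_interaction(cohort.outcome, cohort.month, cohort.m)
            exact = summarize_interaction(fit, reference_amplitude=0.5)
            lin = summarize_interaction(
                fit, reference_amplitude=0.5, definition="linear"
            )
            num = abs(exact.delta_amplitude_pct.estimate - lin.delta_amplitude_pct.estimate)
            rel_diffs.append(num / abs(exact.delta_amplitude_pct.estimate))
        assert rel_diffs[-1] < rel_diffs[0]
        assert rel_diffs[-1] < 0.02

    def test_acrophase_wrapped_to_half_year(self):
        cohort, _ = make_marker_cohort(amplitude=0.5, acrophase_shift=np.pi)
        fit = fit_interaction(cohort.outcome, cohort.month, cohort.m)
        s = summarize_interaction(fit)
        assert -6 < s.delta_acrophase_months.estimate <= 6

    def test_bad_reference(self):
        cohort, _ = make_marker_cohort(amplitude=0.5)
        fit = fit_interaction(cohort.outcome, cohort.month, cohort.m)
        with pytest.raises(ValueError, match="reference_amplitude"):
            summarize_interaction(fit, reference_amplitude=0.0)


class TestRunScan:
    def _toy(self, rng, n=400, m=10):
        months = rng.integers(1, 13, size=n)
        angle = 2 * np.pi * (months - 1) / 12
        y = 0.3 * np.cos(angle) + rng.normal(size=n)
        markers = pd.DataFrame(
            rng.binomial(1, 0.4, size=(n, m)).astype(float),
            columns=[f"x{i:03d}" for i in range(m)],
        )
        return y, months, markers

    def test_phewas_bookkeeping_640(self, rng):
        y, months, markers = self._toy(rng, n=300, m=640)
        result = run_scan(y, months, markers)
        assert result.n_tests == 1920  # 3 characteristics x 640 diseases
        assert result.threshold == pytest.approx(0.05 / 1920)

    def test_duplicate_marker_identical_rows(self, rng):
        y, months, markers = self._toy(rng)
        markers["dup"] = markers["x000"]
        result = run_scan(y, months, markers)
        a = result.table.set_index("marker").loc["x000"]
        b = result.table.set_index("marker").loc["dup"]
        cols = [c for c in result.table.columns if c not in ("marker", "p_adjusted")]
        for c in cols:
            assert a[c] == b[c]

    def test_empty_markers_error(self, rng):
        y, months, _ = self._toy(rng)
        with pytest.raises(ValueError, match="empty"):
            run_scan(y, months, pd.DataFrame(index=range(len(y))))

    def test_all_null_scan_rarely_significant(self, rng):
        y, months, markers = self._toy(rng, n=500, m=100)
        result = run_scan(y, months, markers)
        assert result.table["significant"].sum() <= 1

    def test_bonferroni_recount(self, rng):
        y, months, markers = self._toy(rng, n=400, m=50)
        result = run_scan(y, months, markers, settings=ScanSettings(alpha=0.5))
        min_p = result.table[
            ["amplitude_p", "acrophase_p", "displacement_p"]
        ].min(axis=1)
        recount = (np.minimum(min_p * result.n_tests, 1.0) < 0.5).sum()
        assert result.table["significant"].sum() == recount

    def test_fixed_threshold_policy(self, rng):
        y, months, markers = self._toy(rng, n=400, m=20)
        settings = ScanSettings(policy="fixed", threshold=0.0001)
        result = run_scan(y, months, markers, settings=settings)
        assert result.n_tests == 60
        assert result.threshold == 0.0001
        min_p = result.table[
            ["amplitude_p", "acrophase_p", "displacement_p"]
        ].min(axis=1)
        assert (result.table["significant"] == (min_p < 0.0001)).all()

    def test_sorted_by_p(self, rng):
        y, months, markers = self._toy(rng, n=400, m=30)
        result = run_scan(y, months, markers)
        min_p = result.table[
            ["amplitude_p", "acrophase_p", "displacement_p"]
        ].min(axis=1)
        assert (min_p.diff().dropna() >= 0).all()

    def test_degenerate_marker_skipped(self, rng):
        y, months, markers = self._toy(rng, n=300, m=5)
        markers["const"] = 1.0
        result = run_scan(y, months, markers)
        assert ("const" in [name for name, _ in result.skipped])
        assert len(result.table) == 5
        assert result.n_tests == 18  # bookkeeping counts all submitted markers

    def test_marker_pcs_appended(self, rng):
        y, months, markers = self._toy(rng, n=300, m=6)
        settings = ScanSettings(marker_pcs=3)
        result = run_scan(y, months, markers, settings=settings)
        assert len(result.table) == 6

    def test_fixed_policy_requires_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            ScanSettings(policy="fixed")


class TestIncidentDisease:
    def test_event_after_recruitment(self):
        assert incident_disease_exposure(2010.5, 2008.0) == 1.0

    def test_prevalent_is_missing(self):
        assert np.isnan(incident_disease_exposure(2007.0, 2008.0))

    def test_no_event_is_zero(self):
        assert incident_disease_exposure(np.nan, 2008.0) == 0.0

    def test_event_on_recruitment_day_missing(self):
        assert np.isnan(incident_disease_exposure(2008.0, 2008.0))

    def test_vectorised_with_dates(self):
        events = pd.to_datetime(["2015-01-01", "2005-06-01", None])
        recruit = pd.to_datetime(["2010-01-01"] * 3)
        out = incident_disease_exposure(events.to_numpy(), recruit.to_numpy())
        assert out[0] == 1.0 and np.isnan(out[1]) and out[2] == 0.0


class TestComposites:
    @pytest.mark.parametrize(
        "row,any_d,multi",
        [((1, 0, 0), 1, 0), ((1, 1, 0), 1, 1), ((0, 0, 0), 0, 0), ((1, 1, 1), 1, 1)],
    )
    def test_basic_rows(self, row, any_d, multi):
        out = composite_disease_phenotypes(pd.DataFrame([row]))
        assert out.loc[0, "any_disease"] == any_d
        assert out.loc[0, "multiple_diseases"] == multi

    def test_missing_propagates(self):
        out = composite_disease_phenotypes(
            pd.DataFrame([[np.nan, 0.0], [np.nan, 1.0], [1.0, np.nan]])
        )
        assert np.isnan(out.loc[0, "any_disease"])  # could be prevalent-only
        assert out.loc[1, "any_disease"] == 1.0
        assert out.loc[2, "any_disease"] == 1.0
        assert np.isnan(out.loc[2, "multiple_diseases"])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            composite_disease_phenotypes(pd.DataFrame(index=[0]))


class TestMortality:
    def test_amplitude_ratio_recovered(self):
        cfg = SimulationConfig(
            n_individuals=30_000, seed=21, amplitude_true=0.5, noise_sd=1.0,
            death_spec=DeathSpec(rate=0.3, amplitude_ratio=0.8),
        )
        cohort, _ = generate_cohort(cfg)
        _, summ = mortality_interaction(
            cohort.outcome, cohort.month, cohort.death, cohort.followup_years,
            reference_amplitude=0.5,
        )
        # truth: cases have 20% lower amplitude
        est, se = summ.delta_amplitude_pct.estimate, summ.delta_amplitude_pct.se
        assert abs(est - (-20.0)) < 3 * se

    def test_zero_deaths_error(self, rng):
        months = rng.integers(1, 13, size=100)
        with pytest.raises(ValueError, match="constant"):
            mortality_interaction(
                rng.normal(size=100), months, np.zeros(100), rng.uniform(1, 10, 100)
            )

    def test_followup_in_adjustment(self):
        cfg = SimulationConfig(
            n_individuals=2000, seed=22, amplitude_true=0.5,
            death_spec=DeathSpec(rate=0.2),
        )
        cohort, _ = generate_cohort(cfg)
        fit, _ = mortality_interaction(
            cohort.outcome, cohort.month, cohort.death, cohort.followup_years
        )
        assert "followup_years" in fit.params.index


class TestZscoreCorrelations:
    def _fake_table(self, amp, acr, disp):
        return pd.DataFrame(
            {"amplitude_z": amp, "acrophase_z": acr, "displacement_z": disp}
        )

    def test_duplicated_columns(self, rng):
        z = rng.normal(size=50)
        corr = zscore_correlations(self._fake_table(z, z.copy(), z.copy()))
        assert np.allclose(corr.to_numpy(), 1.0)

    def test_negated_column(self, rng):
        z = rng.normal(size=50)
        corr = zscore_correlations(self._fake_table(z, -z, z))
        assert corr.loc["amplitude", "acrophase"] == pytest.approx(-1.0)

    def test_independent_columns_small(self, rng):
        corr = zscore_correlations(
            self._fake_table(*rng.normal(size=(3, 500)))
        )
        off = corr.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.15)
        assert np.allclose(np.diag(corr), 1.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            zscore_correlations(
                self._fake_table(np.ones(5), np.arange(5.0), np.arange(5.0))
            )

    def test_too_few_markers(self, rng):
        with pytest.raises(ValueError):
            zscore_correlations(self._fake_table([1.0], [1.0], [1.0]))


class TestLambdaGC:
    def test_all_half(self):
        assert lambda_gc([0.5] * 100) == pytest.approx(1.0)

    def test_uniform_near_one(self):
        p = np.random.default_rng(0).uniform(size=10_000)
        assert lambda_gc(p) == pytest.approx(1.0, abs=0.03)

    def test_halving_inflates(self, rng):
        p = rng.uniform(size=5000)
        assert lambda_gc(p / 2) > lambda_gc(p)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            lambda_gc([])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            lambda_gc([0.0, 0.5])


class TestParameterRecoverySmoke:
    def test_binary_marker_recovery_single(self):
        # full 200-replicate version lives in the acceptance suite
        cohort, truth = make_marker_cohort(
            seed=3, n=5000, noise=1.0, amplitude=0.5,
            amplitude_change=-0.15, acrophase_shift=0.2, displacement=0.1,
        )
        fit = fit_interaction(cohort.outcome, cohort.month, cohort.m)
        s = summarize_interaction(fit, reference_amplitude=0.5)
        mt = truth.markers["m"]
        assert abs(
            s.delta_amplitude_pct.estimate - 100 * mt.delta_amplitude / 0.5
        ) < 3 * s.delta_amplitude_pct.se
        months_truth = mt.delta_acrophase * 12 / (2 * np.pi)
        assert abs(s.delta_acrophase_months.estimate - months_truth) < \
            3 * s.delta_acrophase_months.se
        assert abs(s.displacement.estimate - mt.displacement) < 3 * s.displacement.se
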