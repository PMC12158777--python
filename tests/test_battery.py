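"""Model battery: OLS contracts, covariate logic, equivalence, flags."""

import numpy as np
import pandas as pd
import pytest

import compositebias as cb
from compositebias import names as N
from compositebias.battery import (
    BIRTH_EXPOSURES,
    battery_covariates,
    reliable_reference,
)

from _oracles import normal_equations_fit


def random_cohort(rng, n=60, k=3):
    """Small random regression dataset with named columns."""
    cols = {f"x{i}": rng.normal(size=n) for i in range(k)}
    cols["baseline"] = rng.normal(10.0, 2.0, size=n)
    cols["exposure"] = rng.normal(size=n)
    cols["follow"] = (cols["baseline"] * rng.uniform(0.5, 1.5)
                      + cols["exposure"] * rng.uniform(-2, 2)
                      + rng.normal(size=n))
    return pd.DataFrame(cols)


class TestFitLinear:
    def test_exact_linear_data_recovered_exactly(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        df["y"] = 2.0 * df["x"] + 1.0
        fit = cb.fit_linear(df, cb.ModelSpec("y", "x", ()))
        assert fit.term("x").coef == pytest.approx(2.0, abs=1e-10)
        assert fit.term("const").coef == pytest.approx(1.0, abs=1e-10)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-16)

    def test_identity_regression_has_degenerate_ci_at_one(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        df["y"] = df["x"]
        fit = cb.fit_linear(df, cb.ModelSpec("y", "x", ()))
        t = fit.term("x")
        assert t.coef == pytest.approx(1.0, abs=1e-12)
        assert t.ci_low == pytest.approx(1.0, abs=1e-8)
        assert t.ci_high == pytest.approx(1.0, abs=1e-8)

    def test_rank_deficiency_names_the_collinear_columns(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["x2"] = 2.0 * df["x"]
        df["y"] = df["x"] + rng.normal(size=30)
        with pytest.raises(ValueError, match="collinear") as err:
            cb.fit_linear(df, cb.ModelSpec("y", "x", ("x2",)))
        assert "x" in str(err.value)

    def test_missing_column_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="lacks"):
            cb.fit_linear(df, cb.ModelSpec("y", "x", ()))

    def test_incomplete_rows_dropped_and_counted(self):
        rng = np.random.default_rng(1)
        df = random_cohort(rng, n=40)
        df.loc[3, "exposure"] = np.nan
        fit = cb.fit_linear(df, cb.ModelSpec("follow", "exposure", ("baseline",)))
        assert fit.n == 39 and fit.n_dropped == 1

    def test_confidence_interval_brackets_coefficient(self):
        rng = np.random.default_rng(2)
        fit = cb.fit_linear(random_cohort(rng),
                            cb.ModelSpec("follow", "exposure", ("baseline",)))
        for t in fit.terms.values():
            assert t.ci_low <= t.coef <= t.ci_high

    def test_model_spec_forbids_outcome_on_rhs(self):
        with pytest.raises(ValueError):
            cb.ModelSpec("y", "x", ("y",))
        with pytest.raises(ValueError):
            cb.ModelSpec("y", "x", ("x",))


class TestEquivalence:
    def test_identity_holds_on_random_cohorts(self):
        """Translating the outcome by a regressor shifts only that
        regressor's coefficient, by exactly -1."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            df = random_cohort(rng, n=int(rng.integers(20, 120)))
            rep = cb.equivalence_check(df, "exposure", "baseline", "follow",
                                       ("baseline", "x0", "x1"))
            assert abs(rep.exposure_coef_difference) < 1e-8
            assert abs(rep.baseline_coef_difference + 1.0) < 1e-8

    def test_identity_exact_on_hand_constructed_integers(self):
        df = pd.DataFrame({
            "exposure": [0.0, 1, 0, 1, 0, 1],
            "baseline": [60.0, 70, 80, 90, 100, 110],
            "follow":   [66.0, 75, 83, 95, 104, 118],
        })
        rep = cb.equivalence_check(df, "exposure", "baseline", "follow",
                                   ("baseline",))
        # independent check straight from the normal equations
        X = np.column_stack([np.ones(6), df["exposure"], df["baseline"]])
        beta_follow = normal_equations_fit(X, df["follow"].to_numpy())
        beta_change = normal_equations_fit(
            X, (df["follow"] - df["baseline"]).to_numpy())
        assert beta_change[1] == pytest.approx(beta_follow[1], abs=1e-10)
        assert beta_change[2] == pytest.approx(beta_follow[2] - 1.0, abs=1e-10)
        assert rep.follow_fit.term("exposure").coef == \
            pytest.approx(beta_follow[1], abs=1e-10)
        assert abs(rep.exposure_coef_difference) < 1e-10
        assert abs(rep.baseline_coef_difference + 1.0) < 1e-10

    def test_identity_requires_baseline_adjustment(self):
        rng = np.random.default_rng(4)
        df = random_cohort(rng)
        with pytest.raises(ValueError, match="baseline"):
            cb.equivalence_check(df, "exposure", "baseline", "follow", ("x0",))
        # counterexample: without the baseline the coefficients genuinely differ
        follow = cb.fit_linear(df, cb.ModelSpec("follow", "exposure", ("x0",)))
        df["change"] = df["follow"] - df["baseline"]
        change = cb.fit_linear(df, cb.ModelSpec("change", "exposure", ("x0",)))
        assert abs(follow.term("exposure").coef
                   - change.term("exposure").coef) > 1e-4


class TestRunBattery:
    def test_post_baseline_covariates_are_the_study_conditioning_set(
            self, cohort_5k, study_dag):
        report = cb.run_battery(cohort_5k, N.ECONOMIC_STATUS, study_dag)
        assert set(report.covariates) == {N.ETHNICITY, N.SEX, N.HEIGHT_SELF,
                                          N.WEIGHT_BASE}
        for outcome, fit in report.results.items():
            assert set(fit.spec.covariates) == set(report.covariates)
            assert N.BMI_BASE not in fit.spec.covariates

    def test_birth_exposure_covariates_free_of_baseline_body_size(
            self, cohort_5k, study_dag):
        report = cb.run_battery(cohort_5k, N.ETHNICITY, study_dag)
        assert set(report.covariates) == {N.SEX}

    def test_report_has_exactly_six_outcome_rows(self, cohort_5k, study_dag):
        report = cb.run_battery(cohort_5k, N.MALAISE, study_dag)
        assert tuple(report.results) == N.BATTERY_OUTCOMES
        assert len(report.to_frame()) == 6

    def test_composite_exposure_rejected(self, cohort_5k, study_dag):
        with pytest.raises(ValueError, match="one-to-many"):
            cb.run_battery(cohort_5k, N.BMI_BASE, study_dag)

    def test_missing_cohort_column_rejected(self, cohort_5k, study_dag):
        with pytest.raises(ValueError, match="lacks"):
            cb.run_battery(cohort_5k.drop(columns=[N.MALAISE]), N.MALAISE,
                           study_dag)

    def test_followup_weight_and_weight_change_estimates_identical(
            self, cohort_5k, study_dag):
        """Both outcomes adjust baseline weight, so the estimates coincide
        exactly for post-baseline exposures."""
        for exposure in (N.ECONOMIC_STATUS, N.MALAISE):
            report = cb.run_battery(cohort_5k, exposure, study_dag)
            a = report.estimate(N.WEIGHT_FOLLOW)
            b = report.estimate(N.WEIGHT_CHANGE)
            assert a.coef == pytest.approx(b.coef, abs=1e-8)
            assert a.se == pytest.approx(b.se, abs=1e-8)

    def test_birth_pattern_negative_reliable_nullish_bmi_positive_changes(
            self, cohort_5k, study_dag, default_scm):
        report = cb.run_battery(cohort_5k, N.ETHNICITY, study_dag,
                                scm=default_scm, truth_n=50_000)
        assert report.reference < 0
        assert report.estimate(N.WEIGHT_FOLLOW).coef < 0
        assert "near-null" in report.flags[N.BMI_FOLLOW]
        for outcome in (N.WEIGHT_CHANGE, N.BMI_CHANGE):
            assert report.estimate(outcome).coef > 0
            assert "sign-reversed" in report.flags[outcome]


class TestBiasFlags:
    @staticmethod
    def report_with(coef, se, study_dag, cohort):
        report = cb.run_battery(cohort, N.ECONOMIC_STATUS, study_dag)
        # overwrite the follow-up weight estimate with a crafted one
        fit = report.results[N.WEIGHT_FOLLOW]
        from dataclasses import replace
        from compositebias.battery import TermEstimate
        terms = dict(fit.terms)
        terms[N.ECONOMIC_STATUS] = TermEstimate(coef, se, coef - 2 * se,
                                                coef + 2 * se)
        report.results[N.WEIGHT_FOLLOW] = replace(fit, terms=terms)
        return report

    def test_concordant_estimate_unflagged_with_unit_ratio(
            self, study_dag, cohort_5k):
        report = self.report_with(-3.0, 0.5, study_dag, cohort_5k)
        flagged = cb.bias_flags(report, reference=-3.0)
        assert flagged.flags[N.WEIGHT_FOLLOW] == ()
        assert flagged.dilution[N.WEIGHT_FOLLOW] == pytest.approx(1.0)

    def test_opposite_sign_beyond_noise_is_sign_reversed(
            self, study_dag, cohort_5k):
        report = self.report_with(0.5, 0.1, study_dag, cohort_5k)
        assert "sign-reversed" in cb.bias_flags(
            report, reference=-3.0).flags[N.WEIGHT_FOLLOW]

    def test_estimate_within_noise_is_near_null(self, study_dag, cohort_5k):
        report = self.report_with(-0.05, 0.2, study_dag, cohort_5k)
        assert "near-null" in cb.bias_flags(
            report, reference=-3.0).flags[N.WEIGHT_FOLLOW]

    def test_same_sign_small_magnitude_is_diluted(self, study_dag, cohort_5k):
        report = self.report_with(-1.0, 0.2, study_dag, cohort_5k)
        assert "diluted" in cb.bias_flags(
            report, reference=-3.0).flags[N.WEIGHT_FOLLOW]

    def test_zero_reference_restricts_to_near_null(self, study_dag, cohort_5k):
        report = self.report_with(0.5, 0.1, study_dag, cohort_5k)
        flagged = cb.bias_flags(report, reference=0.0)
        assert flagged.flags[N.WEIGHT_FOLLOW] == ()
        report = self.report_with(0.1, 0.2, study_dag, cohort_5k)
        assert cb.bias_flags(report, reference=0.0).flags[N.WEIGHT_FOLLOW] == \
            ("near-null",)


class TestSensitivity:
    def test_height_source_swap_moves_estimates_when_error_present(
            self, cohort_5k, study_dag):
        base = cb.run_battery(cohort_5k, N.ECONOMIC_STATUS, study_dag)
        swap, = cb.sensitivity_battery(cohort_5k, N.ECONOMIC_STATUS, study_dag,
                                       variants=("height-source-swap",))
        assert N.HEIGHT_MEASURED in swap.covariates
        diff = abs(base.estimate(N.WEIGHT_FOLLOW).coef
                   - swap.estimate(N.WEIGHT_FOLLOW).coef)
        assert diff > 0

    def test_variants_agree_exactly_when_self_report_error_is_zero(
            self, default_scm, study_dag):
        scm = default_scm.with_overrides(
            {N.SELF_REPORT_ERROR: {"noise_sd": 0.0}})
        cohort = cb.simulate(scm, cb.ScenarioConfig(n=2000, seed=12))
        base = cb.run_battery(cohort, N.ECONOMIC_STATUS, study_dag)
        swap, = cb.sensitivity_battery(cohort, N.ECONOMIC_STATUS, study_dag,
                                       variants=("height-source-swap",))
        for outcome in N.BATTERY_OUTCOMES:
            assert base.estimate(outcome).coef == pytest.approx(
                swap.estimate(outcome).coef, abs=1e-8)

    def test_dropping_baseline_adjustment_reverses_sign_under_confounding(
            self, study_dag):
        scm = cb.confounded_malaise_scenario()
        cohort = cb.simulate(scm, cb.ScenarioConfig(n=20_000, seed=5))
        adjusted = cb.run_battery(cohort, N.MALAISE, study_dag)
        raw, = cb.sensitivity_battery(cohort, N.MALAISE, study_dag,
                                      variants=("no-baseline-adjustment",),
                                      scm=scm)
        assert N.WEIGHT_BASE not in raw.covariates
        flipped = [o for o in N.BATTERY_OUTCOMES
                   if adjusted.estimate(o).coef * raw.estimate(o).coef < 0]
        assert flipped
        assert any("sign-reversed" in raw.flags[o] for o in N.BATTERY_OUTCOMES)

    def test_unknown_variant_rejected(self, cohort_5k, study_dag):
        with pytest.raises(ValueError, match="unknown"):
            cb.sensitivity_battery(cohort_5k, N.MALAISE, study_dag,
                                   variants=("robust-se",))


class TestReference:
    def test_binary_reference_uses_interventional_contrast(self, default_scm):
        ref = reliable_reference(default_scm, N.ECONOMIC_STATUS, n=50_000, seed=9)
        eff = cb.true_effect_by_intervention(default_scm, N.ECONOMIC_STATUS,
                                             0.0, 1.0, n=50_000, seed=9)
        assert ref == eff[N.WEIGHT_FOLLOW].value

    def test_continuous_reference_uses_path_tracing(self, default_scm):
        assert reliable_reference(default_scm, N.WEIGHT_BASE) == \
            cb.true_total_effect(default_scm, N.WEIGHT_BASE, N.WEIGHT_FOLLOW)

    def test_proxy_reference_traces_the_latent(self, default_scm):
        assert reliable_reference(default_scm, N.HEIGHT_SELF) == \
            cb.true_total_effect(default_scm, N.TRUE_HEIGHT, N.WEIGHT_FOLLOW)

    def test_every_battery_exposure_has_dag_covariates(self, study_dag):
        for exposure in N.BATTERY_EXPOSURES:
            covs = battery_covariates(study_dag, exposure)
            if exposure in BIRTH_EXPOSURES:
                assert not set(covs) & {N.WEIGHT_BASE, N.HEIGHT_SELF}
            else:
                assert N.ETHNICITY in covs and N.SEX in covs
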