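"""Objective function, staged fits, tuning intervals and reproducibility."""

import numpy as np
import pytest

from pactmab.calibration import (
    CalibrationError,
    ParamBounds,
    RecoveryReport,
    fit_combination,
    fit_controls,
    fit_pretreatment,
    fit_single_drug,
    global_default_bounds,
    predict_confluence,
    tuning_bounds,
    weighted_l2,
)
from pactmab.dataset import ConfluenceDataset
from pactmab.generate import (
    GeneratorSpec,
    NoiseModel,
    default_truth,
    generate_dataset,
)
from pactmab.model import ModelParams
from pactmab.regimen import build_schedule


class TestWeightedL2:
    def test_zero_iff_model_equals_data(self):
        m = np.array([0.3, 0.4, 0.5])
        w = np.array([0.02, 0.02, 0.02])
        assert weighted_l2(m, m, w) == 0.0
        assert weighted_l2(m + 1e-3, m, w) > 0.0

    def test_single_unit_weighted_residual(self):
        # one timepoint with M - O equal to the CI half-width -> exactly 1
        assert weighted_l2([0.42], [0.40], [0.02]) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # residuals (1, 2) at unit weights -> sqrt(5)
        assert weighted_l2([1.0, 2.0], [0.0, 0.0], [1.0, 1.0]) == pytest.approx(
            np.sqrt(5)
        )

    def test_zero_weight_floored_not_divided(self):
        # a zero CI half-width falls back to the 1e-3 floor
        v = weighted_l2([0.401], [0.4], [0.0])
        assert v == pytest.approx(1e-3 / 1e-3)


class TestBounds:
    def test_global_default_bounds_scale_with_anchors(self):
        b = global_default_bounds(("k", "theta"))
        assert b["k"] == (1e-6, pytest.approx(8.3))
        assert b["theta"] == (1e-6, pytest.approx(6.7))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParamBounds({"k": (1.0, 0.5)})

    def test_tuning_interval_arithmetic(self):
        rep = RecoveryReport.from_errors({"delta_P": 2.0})
        tb = tuning_bounds({"delta_P": 10.0}, rep)
        assert tb["delta_P"] == (pytest.approx(9.8), pytest.approx(10.2))

    def test_zero_error_gives_degenerate_interval(self):
        rep = RecoveryReport.from_errors({"delta_P": 0.0})
        tb = tuning_bounds({"delta_P": 10.0}, rep)
        assert tb["delta_P"] == (10.0, 10.0)

    def test_missing_parameter_in_report_raises(self):
        rep = RecoveryReport.from_errors({"delta_P": 2.0})
        with pytest.raises(KeyError):
            tuning_bounds({"eta_A": 1.0}, rep)


class TestControlFits:
    def test_noiseless_control_envelope_contains_truth(self, control_dataset):
        ds, truth = control_dataset
        bounds = fit_controls([ds], margin=0.1, seed=0)
        lo, hi = bounds["k"]
        assert lo <= truth.k <= hi
        lo, hi = bounds["theta"]
        assert lo <= truth.theta <= hi
        assert bounds.provenance == "control-derived"

    def test_identical_sets_give_margin_only_envelope(self, control_dataset):
        ds, _ = control_dataset
        b = fit_controls([ds, ds], margin=0.2, seed=0)
        lo, hi = b["k"]
        # same set twice: zero-width envelope before the multiplicative margin
        assert hi / lo == pytest.approx(1.2 / 0.8, rel=1e-3)

    def test_non_growing_control_falls_back_to_global(self):
        times = np.linspace(0, 4, 33)
        flat = ConfluenceDataset("flat", times, np.full((4, 33), 0.5))
        with pytest.warns(UserWarning, match="not growing"):
            b = fit_controls([flat])
        assert b.provenance == "global-default"

    def test_no_controls_is_an_error(self):
        with pytest.raises(CalibrationError):
            fit_controls([])


class TestPretreatment:
    def test_recovers_growth_parameters_from_first_day(self, control_dataset):
        ds, truth = control_dataset
        bounds = ParamBounds(
            {"k": (0.4, 1.6), "theta": (0.4, 1.3)}, provenance="control-derived"
        )
        res = fit_pretreatment(ds, bounds, seed=0)
        assert res.params.k == pytest.approx(truth.k, rel=0.01)
        assert res.params.theta == pytest.approx(truth.theta, rel=0.01)

    def test_flat_data_flags_unidentifiable_growth_rate(self):
        times = np.linspace(0, 1, 9)
        ds = ConfluenceDataset("sat", times, np.full((4, 9), 0.67))
        bounds = ParamBounds({"k": (0.4, 1.6), "theta": (0.4, 1.3)})
        res = fit_pretreatment(ds, bounds, seed=0)
        assert any("unidentifiable" in f for f in res.flags)

    def test_zero_width_bounds_return_the_bound_value(self, control_dataset):
        ds, _ = control_dataset
        bounds = ParamBounds({"k": (0.9, 0.9), "theta": (0.7, 0.7)})
        res = fit_pretreatment(ds, bounds, seed=0)
        assert res.params.k == 0.9 and res.params.theta == 0.7
        assert np.isfinite(res.objective)

    def test_too_few_timepoints_rejected(self):
        ds = ConfluenceDataset("short", [0.0, 2.0], np.full((2, 2), 0.5))
        with pytest.raises(CalibrationError):
            fit_pretreatment(ds, ParamBounds({"k": (0.4, 1.6), "theta": (0.4, 1.3)}))


class TestSingleDrugFit:
    def test_noiseless_recovery_within_two_percent(self, pac25_noiseless):
        ds, truth, reg = pac25_noiseless
        res = fit_single_drug(
            ds, reg, "paclitaxel", truth.k, truth.theta, n_starts=10, seed=0
        )
        for name in res.fitted_names:
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=0.02
            )

    def test_objective_is_self_consistent(self, pac25_noiseless):
        ds, truth, reg = pac25_noiseless
        res = fit_single_drug(
            ds, reg, "paclitaxel", truth.k, truth.theta, n_starts=4, seed=0
        )
        win = ds.window(1.0, 4.0)
        model = predict_confluence(res.params, reg, win.times, float(ds.mean[0]))
        assert res.objective == pytest.approx(
            weighted_l2(model, win.mean, win.ci_halfwidth)
        )

    def test_fitted_values_respect_bounds(self, pac25_noiseless):
        ds, truth, reg = pac25_noiseless
        res = fit_single_drug(
            ds, reg, "paclitaxel", truth.k, truth.theta, n_starts=4, seed=0
        )
        for name in res.fitted_names:
            lo, hi = res.bounds[name]
            assert lo <= getattr(res.params, name) <= hi

    def test_multistart_is_reproducible(self, pac25_noiseless):
        ds, truth, reg = pac25_noiseless
        r1 = fit_single_drug(ds, reg, "paclitaxel", truth.k, truth.theta,
                             n_starts=4, seed=7)
        r2 = fit_single_drug(ds, reg, "paclitaxel", truth.k, truth.theta,
                             n_starts=4, seed=7)
        assert r1.params == r2.params
        assert r1.objective == r2.objective

    def test_unknown_drug_rejected(self, pac25_noiseless):
        ds, truth, reg = pac25_noiseless
        with pytest.raises(CalibrationError):
            fit_single_drug(ds, reg, "cisplatin", truth.k, truth.theta)


class TestCombinationFit:
    def test_null_synergy_recovered(self):
        """Combination data generated with S = 1 fits S close to 1."""
        reg = build_schedule("trastuzumab_first", pac_dose=25.0, tmab_dose=25.0)
        truth = default_truth("trastuzumab_first", pac_dose=25.0, tmab_dose=25.0)
        truth = truth.replace(S=1.0)
        ds, _ = generate_dataset(
            GeneratorSpec(truth=truth, regimen=reg, noise=NoiseModel(scale=0.0), seed=5)
        )
        report = RecoveryReport.from_errors(
            {n: 5.0 for n in ("delta_P", "gamma_P", "t_star_P", "alpha_P",
                              "eta_A", "t_star_A", "beta_A")}
        )
        res = fit_combination(
            ds, reg,
            pac_values={n: getattr(truth, n)
                        for n in ("delta_P", "gamma_P", "t_star_P", "alpha_P")},
            tmab_values={n: getattr(truth, n)
                         for n in ("eta_A", "t_star_A", "beta_A")},
            recovery_report=report,
            k=truth.k, theta=truth.theta,
            n_starts=8, seed=0,
        )
        assert 0.9 <= res.params.S <= 1.1
        assert res.params.S == pytest.approx(1.0, abs=0.05)


class TestVerificationStudy:
    def test_recovery_error_grows_with_noise(self):
        """Median recovery error is non-decreasing in the injected noise
        amplitude (mini study: control + one paclitaxel condition)."""
        from pactmab.calibration import run_verification_study
        from pactmab.generate import panel_conditions

        conds = {
            name: reg
            for name, reg in panel_conditions().items()
            if name in ("control", "pac_25nM")
        }
        medians = []
        for scale in (0.0, 0.01, 0.04):
            rep = run_verification_study(
                conditions=conds, n_sets=3, n_starts=6,
                noise=NoiseModel(scale=scale), seed=9,
            )
            medians.append(rep.median_error_pct)
        assert medians[0] <= medians[1] * 1.05
        assert medians[1] <= medians[2] * 1.05


class TestRecoveryReport:
    def test_summary_statistics_order(self):
        rep = RecoveryReport.from_errors({"a": 1.0, "b": 5.0, "c": 0.2})
        assert rep.max_error_pct >= rep.median_error_pct >= rep.min_error_pct
        assert rep.median_error_pct == 1.0

    def test_frame_round_trip(self):
        rep = RecoveryReport.from_errors({"a": 1.0, "b": 5.0})
        df = rep.to_frame()
        assert list(df.columns) == ["parameter", "mean_abs_pct_error", "n_sets"]
        assert set(df["parameter"]) == {"a", "b"}
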