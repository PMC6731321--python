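"""Confluence dataset container, tidy-CSV round trips and the synthetic
panel generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pactmab.dataset import (
    ConfluenceDataset,
    DatasetError,
    read_confluence_csv,
    write_confluence_csv,
)
from pactmab.generate import (
    GeneratorSpec,
    NoiseModel,
    default_truth,
    generate_dataset,
    generate_panel,
    panel_conditions,
)
from pactmab.model import ModelParams
from pactmab.regimen import build_schedule, default_time_grid, simulate


class TestDataset:
    def test_mean_and_ci_derived_from_replicates(self):
        times = np.array([0.0, 1.0, 2.0])
        vals = np.array([[0.1, 0.2, 0.3], [0.3, 0.4, 0.5]])
        ds = ConfluenceDataset("c", times, vals)
        assert np.allclose(ds.mean, [0.2, 0.3, 0.4])
        tcrit = stats.t.ppf(0.975, 1)
        expected_hw = tcrit * vals.std(axis=0, ddof=1) / np.sqrt(2)
        assert np.allclose(ds.ci_halfwidth, expected_hw)

    def test_window_is_closed_on_both_ends(self):
        times = np.linspace(0, 4, 33)
        ds = ConfluenceDataset("c", times, np.ones((2, 33)) * 0.5)
        win = ds.window(1.0, 4.0)
        assert win.times[0] == 1.0 and win.times[-1] == 4.0
        assert len(win.times) == 25

    def test_csv_round_trip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(0)
        times = np.linspace(0, 4, 33)
        vals = np.clip(0.5 + 0.05 * rng.standard_normal((8, 33)), 0, 1)
        ds = ConfluenceDataset("control", times, vals)
        path = tmp_path / "d.csv"
        write_confluence_csv(ds, path)
        back = read_confluence_csv(path)
        assert back.condition == "control"
        assert np.allclose(back.replicate_values, vals)
        assert back.replicate_values.shape == (8, 33)

    def test_empty_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("")
        with pytest.raises(DatasetError, match="empty"):
            read_confluence_csv(p)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("condition,replicate,time_days\nc,0,0.0\n")
        with pytest.raises(DatasetError, match="missing columns"):
            read_confluence_csv(p)

    def test_out_of_range_confluence_names_rows(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "condition,replicate,time_days,confluence\nc,0,0.0,0.5\nc,0,1.0,1.4\n"
        )
        with pytest.raises(DatasetError, match="rows \\[3\\]"):
            read_confluence_csv(p)

    def test_duplicate_replicate_time_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "condition,replicate,time_days,confluence\n"
            "c,0,0.0,0.5\nc,0,0.0,0.6\n"
        )
        with pytest.raises(DatasetError, match="duplicate"):
            read_confluence_csv(p)


class TestGenerator:
    def test_zero_noise_replicates_equal_truth_curve(self, control_dataset):
        ds, truth = control_dataset
        assert np.allclose(ds.replicate_values, ds.replicate_values[0])
        traj = simulate(truth, build_schedule("control"), t_grid=ds.times)
        assert np.allclose(ds.mean, traj.at_times(ds.times), atol=1e-12)

    def test_same_seed_gives_identical_datasets(self):
        reg = build_schedule("paclitaxel_only", pac_dose=25.0)
        spec = GeneratorSpec(
            truth=default_truth("paclitaxel_only", pac_dose=25.0),
            regimen=reg, noise=NoiseModel(scale=0.02), seed=42,
        )
        d1, _ = generate_dataset(spec)
        d2, _ = generate_dataset(spec)
        assert np.array_equal(d1.replicate_values, d2.replicate_values)

    def test_control_endpoint_near_reported_value(self, control_dataset):
        # defaults (k = 0.83, theta = 0.67, seeding 3.5e4 cells) put the
        # day-4 control confluence in the vicinity of the observed 0.61
        ds, _ = control_dataset
        assert 0.55 <= ds.mean[-1] <= 0.70

    def test_replicate_mean_converges_to_truth(self):
        reg = build_schedule("control")
        spec = GeneratorSpec(
            truth=ModelParams(), regimen=reg,
            noise=NoiseModel(scale=0.05, n_replicates=1000), seed=3,
        )
        ds, truth = spec, None
        ds, truth = generate_dataset(spec)
        traj = simulate(truth, reg, t_grid=ds.times)
        # Monte-Carlo tolerance: 4 sigma of the mean of 1000 draws
        assert np.all(np.abs(ds.mean - traj.at_times(ds.times)) < 4 * 0.05 / np.sqrt(1000) + 5e-3)

    def test_ci_halfwidth_scales_inverse_sqrt_n(self):
        reg = build_schedule("control")
        widths = {}
        for n in (8, 32, 128):
            spec = GeneratorSpec(
                truth=ModelParams(), regimen=reg,
                noise=NoiseModel(scale=0.05, n_replicates=n), seed=11,
            )
            ds, _ = generate_dataset(spec)
            widths[n] = np.median(ds.ci_halfwidth)
        assert widths[8] / widths[32] == pytest.approx(2.0, rel=0.35)
        assert widths[32] / widths[128] == pytest.approx(2.0, rel=0.35)

    def test_panel_layout(self):
        conds = panel_conditions()
        assert len(conds) == 16  # 1 control + 6 pac + 3 tmab + 6 combos
        panel = generate_panel(seed=0, noise=NoiseModel(scale=0.0, n_replicates=2))
        assert set(panel) == set(conds)
        ds, truth, reg = panel["pac_25nM"]
        assert ds.n_replicates == 2
        assert len(ds.times) == 33
        assert truth.delta_P == default_truth("paclitaxel_only", pac_dose=25.0).delta_P

    def test_default_replicate_count_is_eight(self):
        assert NoiseModel().n_replicates == 8

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(kind="lognormal")
        with pytest.raises(ValueError):
            NoiseModel(scale=-0.1)

    def test_day4_ordering_follows_dose(self):
        """Higher doses produce lower day-4 burden across the panel truths."""
        panel = generate_panel(seed=0, noise=NoiseModel(scale=0.0, n_replicates=2))
        pac = [panel[f"pac_{d:g}nM"][0].mean[-1] for d in (10, 25, 50, 100, 250, 500)]
        tmab = [panel[f"tmab_{d:g}ugml"][0].mean[-1] for d in (10, 25, 50)]
        # mild non-monotonicity at the lowest paclitaxel doses mirrors the
        # observed panel (0.45 at 10 nM vs 0.46 at 25 nM)
        assert pac[0] <= panel["control"][0].mean[-1]
        assert all(a >= b - 0.015 for a, b in zip(pac, pac[1:]))
        assert all(a > b for a, b in zip(tmab, tmab[1:]))
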