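from datetime import date

import numpy as np
import pandas as pd
import pytest

import hatchphen as hp
from hatchphen.simulate import (
    ExperimentSpec,
    ReconstructionError,
    RegimeSpec,
    make_regime,
    reconstruct_lab_regimes,
    simulate_experiment,
)


class TestMakeRegime:
    def test_constant_without_jitter(self):
        s = make_regime(RegimeSpec(kind="constant", base_c=5.3, n_days=100))
        assert (s.temps == 5.3).all()
        assert s.temps.sum() == pytest.approx(530.0)

    def test_spike_block_means_exact_at_zero_jitter(self):
        spec = RegimeSpec(
            kind="spike", base_c=3.4, spike_c=10.0, post_spike_c=3.4,
            start=date(2016, 11, 1), spike_start=date(2016, 12, 20),
            spike_duration_d=28, ramp_days=0, n_days=120,
        )
        s = make_regime(spec)
        pre = (date(2016, 12, 20) - date(2016, 11, 1)).days
        assert (s.temps[:pre] == 3.4).all()
        assert (s.temps[pre : pre + 28] == 10.0).all()
        assert (s.temps[pre + 28 :] == 3.4).all()

    def test_spike_ramps_are_linear(self):
        spec = RegimeSpec(
            kind="spike", base_c=4.0, spike_c=10.0, post_spike_c=3.4,
            start=date(2016, 12, 18), spike_start=date(2016, 12, 20),
            spike_duration_d=5, ramp_days=2, n_days=20,
        )
        s = make_regime(spec)
        np.testing.assert_allclose(s.temps[2:4], [6.0, 8.0])  # 4 -> 10 in thirds

    def test_river_deterministic_and_nonnegative(self):
        spec = RegimeSpec(kind="river", seed=5, n_days=500, start=date(2010, 8, 1))
        a, b = make_regime(spec), make_regime(spec)
        np.testing.assert_array_equal(a.temps, b.temps)
        assert (a.temps >= 0).all()
        # boreal seasonality: near-zero winters, warm summers
        assert a.temps.max() > 14.0
        assert (a.temps < 0.5).sum() > 30

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            RegimeSpec(kind="constant", n_days=-5)
        with pytest.raises(ValueError):
            RegimeSpec(kind="spike", spike_duration_d=-1)
        with pytest.raises(ValueError):
            RegimeSpec(kind="nonsense")


class TestReconstruction:
    def test_constant_treatment_tracks_printed_atu(self, lab_regimes, lab_summary):
        # constant cells are pinned to the printed mean temperature, so the
        # ATU residual at DPF50 only reflects rounding/jitter of the summary
        diag = lab_regimes.diagnostics
        a_rows = diag[diag["treatment"] == "A"]
        assert (np.abs(a_rows["atu_at_dpf50"] - a_rows["target_atu50"]) <= 7.0).all()
        # the 1 Nov constant cell: 99 days at 5.3 °C gives 524.7 ATU vs printed 526
        row = a_rows.iloc[0]
        assert row["atu_at_dpf50"] == pytest.approx(524.7, abs=0.01)
        assert abs(row["atu_at_dpf50"] - row["target_atu50"]) <= 2.0

    def test_spike_cells_hit_printed_atu_exactly(self, lab_regimes):
        diag = lab_regimes.diagnostics
        bc = diag[diag["treatment"].isin(["B", "C"])]
        assert np.allclose(bc["atu_at_dpf50"], bc["target_atu50"], atol=1e-6)

    def test_mean_residuals_within_tolerance(self, lab_regimes):
        assert (np.abs(lab_regimes.diagnostics["mean_residual_c"]) <= 0.5).all()

    def test_cold_spike_pre_levels_near_constant_treatment(self, lab_regimes):
        # the solved pre-spike levels for the cold treatment sit near the
        # shared pre-spike tank temperature (~5.3 °C)
        diag = lab_regimes.diagnostics
        c_pre = diag[diag["treatment"] == "C"]["pre_spike_c"]
        assert ((c_pre > 4.5) & (c_pre < 6.5)).all()

    def test_spike_equal_to_baseline_reduces_to_constant(self):
        summary = pd.DataFrame(
            [{"fert_date": date(2016, 11, 1), "treatment": "B",
              "mean_temp_c": 5.3, "atu50": 530.0, "dpf50": 100}]
        )
        rec = reconstruct_lab_regimes(
            summary, spike_levels={"B": 5.3}, post_spike_c=5.3
        )
        series = rec[("B", date(2016, 11, 1))]
        np.testing.assert_allclose(series.temps, 5.3)

    def test_infeasible_constraint_raises_naming_it(self):
        summary = pd.DataFrame(
            [{"fert_date": date(2016, 11, 1), "treatment": "B",
              "mean_temp_c": 5.2, "atu50": 2000.0, "dpf50": 100}]
        )
        with pytest.raises(ReconstructionError, match="ATU constraint"):
            reconstruct_lab_regimes(summary)


class TestSimulateExperiment:
    def test_degenerate_noise_hatches_on_the_true_day(self, lab_regimes):
        spec = ExperimentSpec(
            n_families=2, tubes_per_treatment={"A": 1}, family_sd=0.0,
            tube_sd=0.0, egg_scale=0.0, success_range=(1.0, 1.0), seed=1,
        )
        ds = simulate_experiment(spec, lab_regimes)
        for tube in ds.records:
            hatched = tube.obs[tube.obs["n_hatched_new"] > 0]
            assert len(hatched) == 1  # every egg on the same day
            assert hatched["n_hatched_new"].iloc[0] == 50
            series = ds.series_for(tube)
            traj = hp.accumulate(series, spec.true_model, tube.fert_date, events=["hatch50"])
            true_day = int(traj.event("hatch50").fractional_day_offset)
            obs_day = (hatched["obs_date"].iloc[0].date() - tube.fert_date).days
            assert obs_day == true_day

    def test_full_success_means_no_dead_eggs(self, lab_regimes):
        spec = ExperimentSpec(n_families=3, success_range=(1.0, 1.0), seed=2)
        ds = simulate_experiment(spec, lab_regimes)
        assert all(t.obs["n_dead_new"].sum() == 0 for t in ds.records)

    def test_counts_bounded_and_cumulative_nondecreasing(self, lab_regimes):
        spec = ExperimentSpec(n_families=5, seed=3)
        ds = simulate_experiment(spec, lab_regimes)
        for t in ds.records:
            cum = t.obs["n_hatched_new"].cumsum()
            assert (cum.diff().dropna() >= 0).all()
            assert cum.iloc[-1] + t.obs["n_dead_new"].sum() <= 50

    def test_fixed_seed_gives_byte_identical_csv(self, lab_regimes, tmp_path):
        spec = ExperimentSpec(n_families=4, seed=11)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        simulate_experiment(spec, lab_regimes).to_csv(p1)
        simulate_experiment(spec, lab_regimes).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_regime_too_short_raises(self):
        short = {"A": hp.TemperatureSeries.from_values(date(2016, 11, 1), np.full(30, 5.3))}
        spec = ExperimentSpec(n_families=1, tubes_per_treatment={"A": 1}, seed=4)
        with pytest.raises(ValueError, match="too short"):
            simulate_experiment(spec, short)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ExperimentSpec(family_sd=-1.0)
        with pytest.raises(ValueError):
            ExperimentSpec(success_range=(0.8, 0.2))
        with pytest.raises(ValueError):
            ExperimentSpec(egg_distribution="cauchy")


def test_end_to_end_identifiability_low_noise(lab_regimes):
    """With the generating model also used for prediction, observed-minus-
    predicted ATU vanishes as the noise terms go to zero."""
    spec = ExperimentSpec(
        n_families=8, tubes_per_treatment={"A": 2, "B": 1, "C": 1},
        family_sd=0.5, tube_sd=0.5, egg_scale=0.5, success_range=(0.9, 1.0),
        seed=21,
    )
    ds = simulate_experiment(spec, lab_regimes)
    estimates, skipped = hp.fit_all_tubes(ds)
    assert not skipped
    frame = hp.hatch.estimates_to_frame(estimates)
    cells = frame.groupby(["treatment", "fert_date"], as_index=False)["atu50"].mean()
    cells["fert_date"] = pd.to_datetime(cells["fert_date"]).dt.date
    model = spec.true_model
    diffs = []
    for _, row in cells.iterrows():
        series = lab_regimes[(row["treatment"], row["fert_date"])]
        traj = hp.accumulate(series, model, row["fert_date"], events=["hatch50"])
        diffs.append(row["atu50"] - traj.event("hatch50").atu_at_event)
    # within one day's worth of thermal units (daily count discretization)
    assert abs(np.mean(diffs)) < 6.0
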