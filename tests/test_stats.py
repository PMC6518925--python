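import shutil
import subprocess
import textwrap
from datetime import date

import numpy as np
import pandas as pd
import pytest

import hatchphen as hp
from hatchphen.stats import (
    EvaluationError,
    collapse_replicates,
    evaluate_models,
    fit_family_model,
    fit_treatment_model,
    icc_oneway,
    paired_t,
)


# ---------------------------------------------------------------------------
# One-way ICC
# ---------------------------------------------------------------------------

def icc_bruteforce(values, groups):
    """Definitional one-way ANOVA ICC, written with explicit loops."""
    by_group = {}
    for v, g in zip(values, groups):
        by_group.setdefault(g, []).append(v)
    k = len(by_group)
    n = len(values)
    grand = sum(values) / n
    ssb = sum(len(vs) * (sum(vs) / len(vs) - grand) ** 2 for vs in by_group.values())
    ssw = sum(
        (v - sum(vs) / len(vs)) ** 2 for vs in by_group.values() for v in vs
    )
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    k0 = (n - sum(len(vs) ** 2 for vs in by_group.values()) / n) / (k - 1)
    return (msb - msw) / (msb + (k0 - 1) * msw)


def test_icc_one_for_zero_within_group_variance():
    res = icc_oneway([1, 1, 2, 2, 3, 3], ["a", "a", "b", "b", "c", "c"])
    assert res.icc == pytest.approx(1.0)
    assert res.ci_low <= res.icc <= res.ci_high


def test_icc_near_zero_without_group_effect():
    rng = np.random.default_rng(3)
    values = rng.normal(0, 1, 60)
    groups = np.repeat(np.arange(12), 5)
    res = icc_oneway(values, groups)
    assert -0.3 < res.icc < 0.3  # may be slightly negative; reported as computed


def test_icc_matches_hand_computed_anova_table():
    # fixed 4-group x 3-replicate table
    values = [10.0, 11.0, 12.0, 20.0, 19.0, 21.0, 15.0, 14.0, 16.0, 30.0, 29.0, 31.0]
    groups = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3 + ["g4"] * 3
    res = icc_oneway(values, groups)
    assert res.icc == pytest.approx(icc_bruteforce(values, groups), rel=1e-12)
    assert res.n_groups == 4
    assert res.mean_group_size == 3.0


def test_icc_equals_bruteforce_on_all_balanced_designs_up_to_6x6():
    rng = np.random.default_rng(12345)
    for k in range(2, 7):
        for n_rep in range(2, 7):
            values = rng.normal(0, 1, k * n_rep) + np.repeat(rng.normal(0, 1, k), n_rep)
            groups = np.repeat(np.arange(k), n_rep)
            got = icc_oneway(values, groups).icc
            want = icc_bruteforce(list(values), list(groups))
            assert got == pytest.approx(want, rel=1e-10), (k, n_rep)


def test_icc_rejects_degenerate_designs():
    with pytest.raises(ValueError):
        icc_oneway([1.0, 2.0], ["a", "a"])
    with pytest.raises(ValueError):
        icc_oneway([1.0, 2.0, 3.0], ["a", "b", "c"])


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

def simulate_tubes(rng, n_fam=17, n_tubes=5, family_sd=10.0, resid_sd=4.0,
                   date_effects=(0.0, 2.0, -1.0, -4.0)):
    dates = ["2016-11-01", "2016-11-04", "2016-11-08", "2016-11-11"]
    rows = []
    for i in range(n_fam):
        fd = dates[i % 4]
        fam_eff = rng.normal(0, family_sd)
        for j in range(n_tubes):
            rows.append(
                {
                    "family_id": f"F{i:02d}",
                    "fert_date": fd,
                    "treatment": "A",
                    "atu50": 527.0 + date_effects[i % 4] + fam_eff + rng.normal(0, resid_sd),
                }
            )
    return pd.DataFrame(rows)


def test_null_family_effect_gives_small_lrt():
    rng = np.random.default_rng(11)
    df = simulate_tubes(rng, family_sd=0.0, resid_sd=10.0)
    res = fit_family_model(df)
    assert res.lrt_chi2 < 3.0
    assert res.lrt_p > 0.05


def test_variance_components_recovered_within_30_percent():
    rng = np.random.default_rng(42)
    vb, ve = [], []
    for _ in range(100):
        df = simulate_tubes(rng, family_sd=10.0, resid_sd=4.0)
        res = fit_family_model(df)
        vb.append(res.random_intercept_variance)
        ve.append(res.residual_variance)
    assert np.mean(vb) == pytest.approx(100.0, rel=0.30)
    assert np.mean(ve) == pytest.approx(16.0, rel=0.30)


def test_translation_moves_only_the_intercept():
    rng = np.random.default_rng(5)
    df = simulate_tubes(rng)
    res = fit_family_model(df)
    df2 = df.assign(atu50=df["atu50"] + 100.0)
    res2 = fit_family_model(df2)
    assert res2.fixed_effects["Intercept"] == pytest.approx(
        res.fixed_effects["Intercept"] + 100.0, abs=1e-4
    )
    assert res2.random_intercept_variance == pytest.approx(
        res.random_intercept_variance, rel=1e-4
    )
    assert res2.residual_variance == pytest.approx(res.residual_variance, rel=1e-4)


def test_lrt_invariant_to_affine_rescaling():
    rng = np.random.default_rng(6)
    df = simulate_tubes(rng)
    res = fit_family_model(df)
    df2 = df.assign(atu50=3.2 * df["atu50"] - 40.0)
    res2 = fit_family_model(df2)
    assert res2.lrt_chi2 == pytest.approx(res.lrt_chi2, abs=2e-2)
    assert res2.lrt_p_halved == pytest.approx(res.lrt_p / 2, rel=1e-6)


def test_boundary_fit_reports_tiny_variance_without_raising():
    # responses carry no family signal and almost no noise: the family
    # variance collapses towards the boundary but nothing raises
    rng = np.random.default_rng(8)
    df = simulate_tubes(rng, family_sd=0.0, resid_sd=0.01)
    res = fit_family_model(df)
    assert res.random_intercept_variance >= 0.0
    assert res.random_intercept_variance < 1e-4
    assert res.lrt_chi2 < 3.0
    if res.singular:
        assert res.lrt_chi2 == 0.0


def test_treatment_model_pre_averages_replicates():
    rng = np.random.default_rng(9)
    df = simulate_tubes(rng)
    for treatment, shift in [("B", -5.0), ("C", -45.0)]:
        extra = df[df["treatment"] == "A"].groupby(
            ["family_id", "fert_date"], as_index=False
        )["atu50"].mean()
        extra["treatment"] = treatment
        extra["atu50"] += shift + rng.normal(0, 4.0, len(extra))
        df = pd.concat([df, extra], ignore_index=True)
    collapsed = collapse_replicates(df)
    # one row per family x treatment after collapsing the replicate treatment
    assert collapsed.groupby(["family_id", "treatment"]).size().max() == 1
    res = fit_treatment_model(df)
    assert "C(treatment)" in res.fixed_tests
    assert "C(treatment):C(fert_date)" in res.fixed_tests
    assert res.fixed_tests["C(treatment)"].p_value < 1e-4


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_satterthwaite_f_test_matches_lmerTest(tmp_path):
    rng = np.random.default_rng(99)
    df = simulate_tubes(rng, n_fam=17, n_tubes=5, family_sd=8.0, resid_sd=5.0)
    # unbalance the design a little, as in the real experiment
    df = df.drop(index=[4, 9, 60]).reset_index(drop=True)
    csv = tmp_path / "tubes.csv"
    df.to_csv(csv, index=False)
    rfile = tmp_path / "check.R"
    rfile.write_text(textwrap.dedent(f"""
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        m <- lmer(atu50 ~ factor(fert_date) + (1 | family_id), data = d)
        a <- anova(m)  # Satterthwaite
        cat(a$`F value`[1], a$DenDF[1], sep = "\\n")
    """))
    out = subprocess.run(
        ["Rscript", "--vanilla", str(rfile)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    f_r, ddf_r = (float(x) for x in out.stdout.strip().splitlines()[-2:])
    res = fit_family_model(df)
    test = res.fixed_tests["C(fert_date)"]
    assert test.method == "satterthwaite"
    assert test.f_stat == pytest.approx(f_r, rel=0.02)
    assert test.df_den == pytest.approx(ddf_r, rel=0.05)


# ---------------------------------------------------------------------------
# Paired t and model evaluation
# ---------------------------------------------------------------------------

def test_paired_t_matches_textbook_formula():
    diffs = np.array([-9.0, -4.5, -11.2, -6.3, -8.8, -2.1, -7.7, -9.9, -5.5, -6.6, -8.1, -4.4])
    res = paired_t(diffs)
    sd = diffs.std(ddof=1)
    assert res.t_stat == pytest.approx(diffs.mean() / (sd / np.sqrt(12)), rel=1e-12)
    assert res.df == 11
    neg = paired_t(-diffs)
    assert neg.t_stat == pytest.approx(-res.t_stat, rel=1e-12)
    assert neg.p_value == pytest.approx(res.p_value, rel=1e-12)


def test_paired_t_constant_shift_recovered():
    rng = np.random.default_rng(1)
    diffs = -7.0 + rng.normal(0, 0.01, 12)
    assert paired_t(diffs).mean_diff == pytest.approx(-7.0, abs=0.01)


def test_paired_t_zero_variance_reported_as_undefined():
    res = paired_t(np.zeros(12))
    assert np.isnan(res.t_stat)
    assert np.isnan(res.p_value)
    assert res.mean_diff == 0.0


def _perfect_observed(model_names, temps=(5.3, 5.2, 3.9, 3.7)):
    rows = []
    for i, t in enumerate(temps):
        model = hp.get_model(model_names[0])
        d = model.days_to_event(t)
        rows.append(
            {
                "treatment": "ABC"[i % 3],
                "fert_date": date(2016, 11, 1 + i),
                "mean_temp_c": t,
                "atu50": d * t,
                "dpf50": d,
            }
        )
    return pd.DataFrame(rows)


def test_perfect_predictions_give_zero_mean_and_undefined_t():
    obs = _perfect_observed(["gorodilov"])
    res = evaluate_models(obs, [hp.get_model("gorodilov")])["gorodilov"]
    assert res.mean_difference == pytest.approx(0.0, abs=1e-9)
    assert np.isnan(res.t_stat)
    assert res.n_pairs == 4


def test_kane_requires_observed_90_percent_column(lab_summary):
    with pytest.raises(EvaluationError, match="atu90"):
        evaluate_models(lab_summary, [hp.get_model("kane")])


def test_profile_mode_refuses_unresolved_events(lab_summary):
    short = {
        (row["treatment"], row["fert_date"]): hp.TemperatureSeries.from_values(
            row["fert_date"], np.full(10, row["mean_temp_c"])
        )
        for _, row in lab_summary.iterrows()
    }
    with pytest.raises(EvaluationError, match="unresolved"):
        evaluate_models(lab_summary, [hp.get_model("gorodilov")], regimes=short, mode="profile")


def test_twelve_pair_evaluation_structure(lab_summary):
    models = [hp.get_model(n) for n in ("crisp", "gorodilov", "winsirp")]
    res = evaluate_models(lab_summary, models)
    for name, ev in res.items():
        assert ev.n_pairs == 12
        assert ev.df == 11
        assert ev.mean_difference < 0  # every model under-predicts ATU at hatch
    # the compensatory-development model is the closest, as in the experiment
    assert abs(res["gorodilov"].mean_difference) < abs(res["winsirp"].mean_difference)
    assert abs(res["winsirp"].mean_difference) < abs(res["crisp"].mean_difference)
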