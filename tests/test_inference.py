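"""Standardization, screens, contrasts, NPI associations, reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phenowatch.inference import (
    ControlStandardizer,
    GroupContrastModel,
    demographic_screen,
    group_contrasts,
    npi_association,
    significance_tier,
    standardize,
    summarize,
)
from phenowatch.simulate import simulate_feature_cohort


# ---------------------------------------------------------------------------
# standardization

def test_two_point_standardization_with_unit_offset():
    # control values {0, e-1} with delta=1: logs {0, 1}, control mean 0 after
    # centering, SD 1 after scaling -> z = {-1/sqrt(2), +1/sqrt(2)} * sqrt(2)
    X = pd.DataFrame({"y": [0.0, np.e - 1.0]})
    est = ControlStandardizer(offset_policy="one").fit(X)
    z = est.transform(X)["y"]
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    assert z.iloc[0] == pytest.approx(-z.iloc[1])


def test_control_z_contract_on_simulated_cohort():
    df = simulate_feature_cohort({"CN": 80, "SCD": 20, "CI": 20},
                                 {"a": {}, "b": {"CI": 1.0}}, seed=3)
    z, _ = standardize(df.rename(columns={"a": "calls_incoming_number",
                                          "b": "apps_all_times_opened"}),
                       df.index[df.group == "CN"])
    for col in z.columns:
        ctrl = z.loc[df.group == "CN", col].dropna()
        assert abs(ctrl.mean()) < 1e-10
        assert abs(ctrl.std(ddof=1) - 1.0) < 1e-10


def test_offset_applied_only_when_zeros_present():
    X = pd.DataFrame({"with_zeros": [0.0, 2.0, 5.0], "positive": [1.0, 2.0, 3.0]})
    est = ControlStandardizer().fit(X)
    assert est.offset_["with_zeros"] == 2.0  # smallest positive observed
    assert est.offset_["positive"] == 0.0
    half = ControlStandardizer(offset_policy="half_min").fit(X)
    assert half.offset_["with_zeros"] == 1.0


def test_degenerate_outcomes_dropped_with_reason():
    X = pd.DataFrame({"constant": [3.0] * 5, "empty": [np.nan] * 5,
                      "fine": [1.0, 2.0, 3.0, 4.0, 5.0]})
    est = ControlStandardizer().fit(X)
    assert est.dropped_["constant"] == "zero_control_sd"
    assert est.dropped_["empty"] == "all_missing_in_controls"
    assert list(est.transform(X).columns) == ["fine"]


def test_standardization_preserves_participant_ranks(rng):
    x = pd.Series(rng.lognormal(0, 1, 50))
    X = pd.DataFrame({"y": x})
    z = ControlStandardizer().fit(X).transform(X)["y"]
    rho, _ = stats.spearmanr(x, z)
    assert rho == pytest.approx(1.0)


def test_affine_rescaling_is_absorbed(rng):
    """km vs m changes nothing after log-standardization when the outcome is
    strictly positive (offset 0)."""
    df = simulate_feature_cohort({"CN": 60, "SCD": 20, "CI": 20},
                                 {"y": {"CI": -0.6}}, seed=4)
    meta = df[["group", "age", "sex", "education_years"]]
    res = {}
    for scale in (1.0, 1000.0):
        scaled = df.copy()
        scaled["y"] = scaled["y"] * scale
        z, _ = standardize(scaled.rename(columns={"y": "loc_mean_distance_traveled"}),
                           df.index[df.group == "CN"])
        res[scale] = group_contrasts(z, meta)
    pd.testing.assert_frame_equal(res[1.0], res[1000.0], atol=1e-9)


def test_missing_values_propagate_not_impute():
    X = pd.DataFrame({"y": [1.0, np.nan, 3.0, 4.0]})
    z = ControlStandardizer().fit(X).transform(X)["y"]
    assert np.isnan(z.iloc[1]) and z.notna().sum() == 3


# ---------------------------------------------------------------------------
# demographic screen

def test_screen_feature_equal_to_age_has_rho_one():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"group": "CN", "age": rng.integers(46, 84, 60),
                       "sex": rng.choice(["female", "male"], 60),
                       "education_years": rng.integers(6, 20, 60)})
    df["calls_incoming_number"] = df["age"].astype(float)
    out = demographic_screen(df)
    row = out[(out.outcome == "calls_incoming_number") & (out.variable == "age")]
    assert row["statistic"].iloc[0] == pytest.approx(1.0)
    assert row["p"].iloc[0] < 1e-10


def test_screen_constant_feature_yields_missing_rho():
    df = pd.DataFrame({"group": "CN", "age": [50, 60, 70, 55],
                       "sex": ["female", "male", "female", "male"],
                       "education_years": [8, 10, 12, 14],
                       "calls_incoming_number": [1.0, 1.0, 1.0, 1.0]})
    out = demographic_screen(df)
    row = out[(out.outcome == "calls_incoming_number") & (out.variable == "age")]
    assert np.isnan(row["statistic"].iloc[0])


def test_screen_skips_sparse_features():
    df = pd.DataFrame({"group": "CN", "age": [50, 60, 70],
                       "sex": ["female", "male", "female"],
                       "education_years": [8, 10, 12],
                       "calls_incoming_number": [1.0, np.nan, np.nan]})
    assert demographic_screen(df).empty


def test_screen_detects_simulated_age_effect():
    """A negative age effect on the rate shows as negative rho with p < .05
    in at least 90% of replicates at n=200."""
    hits = 0
    reps = 60
    for rep in range(reps):
        df = simulate_feature_cohort({"CN": 200}, {"calls_outgoing_number": {}},
                                     seed=5000 + rep, age_effect=0.02)
        out = demographic_screen(df)
        row = out[(out.outcome == "calls_outgoing_number") & (out.variable == "age")]
        hits += (row["statistic"].iloc[0] < 0) and (row["p"].iloc[0] < 0.05)
    assert hits / reps >= 0.9


# ---------------------------------------------------------------------------
# group contrasts

def test_injected_group_effect_recovered():
    betas = []
    for rep in range(25):
        df = simulate_feature_cohort({"CN": 100, "SCD": 30, "CI": 30},
                                     {"y": {"CI": -0.8}}, seed=100 + rep)
        z, _ = standardize(df.rename(columns={"y": "apps_all_times_opened"}),
                           df.index[df.group == "CN"])
        res = group_contrasts(z, df)
        betas.append(res[(res.contrast == "CI-CN")]["beta"].iloc[0])
    assert np.mean(betas) == pytest.approx(-0.8, abs=0.15)


def test_adjustment_removes_age_confounding():
    """Older CI group + age-dependent outcome + no group effect: the
    covariate-adjusted contrast is centered at zero, the unadjusted one is
    biased."""
    adj, unadj = [], []
    for rep in range(30):
        df = simulate_feature_cohort({"CN": 100, "SCD": 30, "CI": 30}, {"y": {}},
                                     seed=200 + rep, age_effect=0.05)
        z, _ = standardize(df.rename(columns={"y": "apps_all_times_opened"}),
                           df.index[df.group == "CN"])
        meta = df[["group", "age", "sex", "education_years"]]
        r_adj = group_contrasts(z, meta)
        r_un = GroupContrastModel(covariates=()).fit(z, meta[["group"]]).results_
        adj.append(r_adj[r_adj.contrast == "CI-CN"]["beta"].iloc[0])
        unadj.append(r_un[r_un.contrast == "CI-CN"]["beta"].iloc[0])
    # CI is ~5 years older; with a negative age effect the unadjusted
    # contrast must be clearly negative while the adjusted one is not
    assert abs(np.mean(adj)) < 0.1
    assert np.mean(unadj) < np.mean(adj) - 0.2


def test_contrasts_report_all_three_pairs_with_bonferroni():
    df = simulate_feature_cohort({"CN": 50, "SCD": 20, "CI": 20}, {"y": {}}, seed=6)
    z, _ = standardize(df.rename(columns={"y": "apps_all_times_opened"}),
                       df.index[df.group == "CN"])
    res = group_contrasts(z, df)
    assert sorted(res["contrast"]) == ["CI-CN", "CI-SCD", "SCD-CN"]
    assert np.allclose(res["p_adj"], np.minimum(1.0, 3 * res["p_raw"]))
    assert (res["cluster"] == "app_use").all()


def test_small_subgroup_flagged_not_silently_dropped():
    df = simulate_feature_cohort({"CN": 40, "SCD": 2, "CI": 20}, {"y": {}}, seed=7)
    z, _ = standardize(df.rename(columns={"y": "apps_all_times_opened"}),
                       df.index[df.group == "CN"])
    res = group_contrasts(z, df)
    scd_row = res[res.contrast == "SCD-CN"].iloc[0]
    assert scd_row["flag"] == "insufficient_n"
    assert np.isnan(scd_row["beta"])
    assert res[res.contrast == "CI-CN"]["flag"].iloc[0] == ""


# ---------------------------------------------------------------------------
# NPI associations

def test_npi_slope_sign_recovered():
    hits = 0
    reps = 40
    for rep in range(reps):
        df = simulate_feature_cohort({"SCD": 20, "CI": 20}, seed=300 + rep,
                                     npi_effects={"loc_mean_distance_traveled": 0.04})
        df = df[df["npi_total"].notna()]
        if len(df) < 12:
            continue
        z, _ = standardize(df, df.index)  # standardize within the available set
        res = npi_association(z, df)
        row = res[res.outcome == "loc_mean_distance_traveled"].iloc[0]
        hits += row["beta"] > 0
    assert hits / reps >= 0.8


def test_shuffled_npi_breaks_association(rng):
    df = simulate_feature_cohort({"SCD": 30, "CI": 30}, seed=8,
                                 npi_effects={"loc_mean_distance_traveled": 0.08})
    df = df[df["npi_total"].notna()]
    z, _ = standardize(df, df.index)
    original = npi_association(z, df)["beta"].iloc[0]
    nulls = []
    for _ in range(30):
        perm = df.copy()
        perm["npi_total"] = rng.permutation(perm["npi_total"].to_numpy())
        nulls.append(npi_association(z, perm)["beta"].iloc[0])
    assert abs(np.mean(nulls)) < abs(original) / 2
    assert original > np.quantile(nulls, 0.9)


def test_constant_npi_flagged():
    df = simulate_feature_cohort({"SCD": 15, "CI": 15}, {"y": {}}, seed=9)
    df["npi_total"] = 4.0
    z, _ = standardize(df.rename(columns={"y": "apps_all_times_opened"}), df.index)
    res = npi_association(z, df)
    assert res["flag"].iloc[0] == "constant_predictor"
    assert np.isnan(res["beta"].iloc[0])


def test_low_n_flagged():
    df = simulate_feature_cohort({"SCD": 30, "CI": 30}, {"y": {}}, seed=10)
    df = df[df["npi_total"].notna()].iloc[:8]
    z, _ = standardize(df.rename(columns={"y": "apps_all_times_opened"}), df.index)
    res = npi_association(z, df)
    assert res["flag"].iloc[0] == "low_n"


# ---------------------------------------------------------------------------
# reporting

@pytest.mark.parametrize("p,tier", [
    (0.004, "**"), (0.0099, "**"), (0.03, "*"), (0.06, "."), (0.51, ""),
    (np.nan, ""),
])
def test_significance_tiers(p, tier):
    assert significance_tier(p) == tier


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1))
def test_tier_function_is_monotone(p1, p2):
    order = {"**": 0, "*": 1, ".": 2, "": 3}
    lo, hi = sorted([p1, p2])
    assert order[significance_tier(lo)] <= order[significance_tier(hi)]


def test_summarize_writes_deterministic_report(tmp_path):
    df = simulate_feature_cohort({"CN": 40, "SCD": 15, "CI": 15},
                                 {"y": {"CI": -0.9}}, seed=11)
    z, _ = standardize(df.rename(columns={"y": "apps_all_times_opened"}),
                       df.index[df.group == "CN"])
    res = group_contrasts(z, df)
    screen = demographic_screen(df.rename(columns={"y": "apps_all_times_opened"}))
    for run in ("r1", "r2"):
        summarize(res, tmp_path / run, screen=screen)
    for name in ("contrasts.csv", "contrasts_tidy.csv", "demographic_screen.csv"):
        assert (tmp_path / "r1" / name).read_bytes() == \
            (tmp_path / "r2" / name).read_bytes()
    assert (tmp_path / "r1" / "contrasts_heatmap.png").exists()
    wide = pd.read_csv(tmp_path / "r1" / "contrasts.csv")
    assert "CI-CN beta (SE)" in wide.columns
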