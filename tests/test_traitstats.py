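"""Trend statistics: back-transformation, mixed/OLS models, KS, contrasts."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhizoflow.synthetic import generate, trend_config
from rhizoflow.traitstats import (DegenerateDataError, TransformationError,
                                  TrendResult, compare_diameter_distributions,
                                  crown_tiller_relation, cultivar_contrasts,
                                  fit_year_trend, percent_change_per_century)


# --- back-transformation ----------------------------------------------------

@pytest.mark.parametrize("slope,expected", [
    (0.0, 0.0),
    (math.log(2) / 100, 100.0),
    (-math.log(2) / 100, -50.0),
])
def test_percent_change_closed_form(slope, expected):
    assert percent_change_per_century(slope) == pytest.approx(expected)


def test_trend_result_enforces_back_transform_invariant():
    with pytest.raises(ValueError, match="inconsistent"):
        TrendResult(trait_name="x", slope_per_year=0.001, p_value=0.5,
                    percent_change_per_century=5.0, model_kind="ols",
                    shapiro_p=0.5)


# --- KS comparisons ---------------------------------------------------------

def test_identical_samples_ks_zero():
    x = np.linspace(0.1, 0.3, 20)
    df = compare_diameter_distributions({"crown": x, "seminal": x})
    assert df["ks_statistic"].iloc[0] == 0.0
    assert df["p_value"].iloc[0] == pytest.approx(1.0)


def test_distinct_root_types_strongly_separated():
    rng = np.random.default_rng(2)
    crown = rng.normal(0.60, 0.05, 30)
    lateral = rng.normal(0.17, 0.05, 30)
    df = compare_diameter_distributions({"crown": crown, "lateral": lateral})
    assert df["p_value"].iloc[0] < 1e-3


def test_ks_input_validation():
    with pytest.raises(DegenerateDataError):
        compare_diameter_distributions({"crown": [0.6] * 10})
    with pytest.raises(DegenerateDataError):
        compare_diameter_distributions({"crown": [0.6] * 10,
                                        "lateral": [0.17] * 3})


# --- year-trend fitting -----------------------------------------------------

def _panel(trait="crown_root_number", pct=-20.0, seed=0, plants=15,
           season_sd=0.08):
    cfg = trend_config(trait=trait, percent_change_per_century=pct,
                       mean_ref=15.0, plants=plants, season_sd=season_sd,
                       seed=seed)
    return generate(cfg).traits


def test_trend_recovery_within_confidence_interval():
    table = _panel(pct=-20.0, seed=31, plants=15)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_year_trend(table, "crown_root_number", random_season=True)
    true_slope = math.log(0.8) / 100.0
    lo, hi = res.slope_ci()
    assert lo <= true_slope <= hi
    assert res.p_value < 0.05
    assert res.percent_change_per_century == pytest.approx(
        (math.exp(100 * res.slope_per_year) - 1) * 100)


def test_mixed_collapses_to_ols_with_single_season():
    table = _panel(seed=5, season_sd=0.0)
    table = table[table["season"] == table["season"].iloc[0]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = fit_year_trend(table, "crown_root_number", random_season=True)
        ols = fit_year_trend(table, "crown_root_number", random_season=False)
    assert mixed.model_kind == "ols"
    assert mixed.slope_per_year == pytest.approx(ols.slope_per_year, rel=1e-8)


@given(st.floats(0.2, 50.0))
@settings(max_examples=20, deadline=None)
def test_trend_slope_equivariant_under_trait_rescaling(c):
    table = _panel(seed=17)
    scaled = table.assign(value=table["value"] * c)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = fit_year_trend(table, "crown_root_number", random_season=False)
        b = fit_year_trend(scaled, "crown_root_number", random_season=False)
    assert b.slope_per_year == pytest.approx(a.slope_per_year, rel=1e-9)
    assert b.p_value == pytest.approx(a.p_value, rel=1e-6)
    assert b.intercept == pytest.approx(a.intercept + math.log(c), rel=1e-6)


def test_nonpositive_values_blocked_with_context():
    table = _panel(seed=1)
    table.loc[table.index[0], "value"] = 0.0
    with pytest.raises(TransformationError, match="crown_root_number"):
        fit_year_trend(table, "crown_root_number")


def test_missing_trait_raises():
    with pytest.raises(KeyError):
        fit_year_trend(_panel(), "no_such_trait")


# --- cultivar contrasts -----------------------------------------------------

def _contrast_panel(elevated="S. Dickkopf", seed=3):
    rng = np.random.default_rng(seed)
    rows = []
    cultivars = [("S. Dickkopf", 1895), ("Jubilar", 1961), ("Tommi", 2002)]
    for cult, year in cultivars:
        mu = 24.0 if cult == elevated else 16.0
        for i in range(12):
            rows.append((f"{cult}-{i}", cult, year, "2022-2023",
                         "axes_number", mu * math.exp(rng.normal(0, 0.12))))
    return pd.DataFrame(rows, columns=["plant_id", "cultivar", "release_year",
                                       "season", "trait_name", "value"])


def test_anova_flat_groups_near_zero_f():
    rows = []
    for cult in ("A", "B", "C"):
        for i in range(5):
            rows.append((f"{cult}{i}", cult, 1900, "s1", "t", 10.0))
    df = pd.DataFrame(rows, columns=["plant_id", "cultivar", "release_year",
                                     "season", "trait_name", "value"])
    anova, tukey = cultivar_contrasts(df, "t")
    p = anova["PR(>F)"].iloc[0]
    assert not np.isfinite(p) or p > 0.5


def test_elevated_oldest_cultivar_detected_by_tukey():
    anova, tukey = cultivar_contrasts(_contrast_panel(), "axes_number")
    assert anova["PR(>F)"].iloc[0] < 1e-3
    vs_old = tukey[(tukey["group1"] == "S. Dickkopf")
                   | (tukey["group2"] == "S. Dickkopf")]
    other = tukey[(tukey["group1"] != "S. Dickkopf")
                  & (tukey["group2"] != "S. Dickkopf")]
    assert (vs_old["p-adj"] < 0.001).all()
    assert (other["p-adj"] > 0.05).all()


def test_two_groups_single_tukey_comparison():
    panel = _contrast_panel()
    panel = panel[panel["cultivar"] != "Jubilar"]
    _, tukey = cultivar_contrasts(panel, "axes_number")
    assert len(tukey) == 1


def test_degenerate_contrast_groups_rejected():
    df = _contrast_panel()
    df = df[df["plant_id"].isin(["S. Dickkopf-0", "Jubilar-0", "Jubilar-1"])]
    with pytest.raises(DegenerateDataError):
        cultivar_contrasts(df, "axes_number")


# --- crown ~ tiller ---------------------------------------------------------

def _crown_tiller_panel(slope=2.3, noise=0.0, seed=0, n=30):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        till = float(rng.integers(3, 9))
        crown = slope * till + rng.normal(0, noise)
        rows.append((f"p{i}", "X", 1900, "s1", "tiller_number", till))
        rows.append((f"p{i}", "X", 1900, "s1", "crown_root_number", crown))
    return pd.DataFrame(rows, columns=["plant_id", "cultivar", "release_year",
                                       "season", "trait_name", "value"])


def test_exact_proportionality_recovered():
    slope, intercept, pv = crown_tiller_relation(_crown_tiller_panel())
    assert slope == pytest.approx(2.3, rel=1e-9)
    assert intercept == pytest.approx(0.0, abs=1e-9)
    assert pv < 1e-12


def test_noisy_positive_relation_significant():
    slope, _, pv = crown_tiller_relation(
        _crown_tiller_panel(slope=2.3, noise=2.0, seed=8))
    assert slope > 0 and pv < 1e-3


def test_constant_tiller_number_rejected():
    df = _crown_tiller_panel()
    df.loc[df["trait_name"] == "tiller_number", "value"] = 5.0
    with pytest.raises(DegenerateDataError):
        crown_tiller_relation(df)
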