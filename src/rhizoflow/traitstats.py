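"""Breeding-trend statistics on root traits.

The analysis chain mirrors standard practice in historical-cultivar panels:

* two-sample Kolmogorov-Smirnov tests compare root-diameter distributions
  between root types;
* release-year trends are fitted on log-transformed plant-level trait
  values — a linear mixed model with the growing season as a random
  intercept for field traits, plain OLS for the hydroponic Krs traits —
  and the slope is back-transformed to a percent change per century,
  (exp(100 * slope_per_year) - 1) * 100;
* cultivar contrasts use one-way ANOVA on log values with Tukey HSD
  adjusted pairwise comparisons;
* residual normality is reported via the Shapiro-Wilk test.

Trait tables are tidy DataFrames with columns plant_id, cultivar,
release_year, season, trait_name, value, holding plant averages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TrendResult",
    "compare_diameter_distributions",
    "fit_year_trend",
    "percent_change_per_century",
    "cultivar_contrasts",
    "crown_tiller_relation",
]

TRAIT_COLUMNS = ("plant_id", "cultivar", "release_year", "season",
                 "trait_name", "value")


class TransformationError(ValueError):
    """Raised when non-positive values block the log transform."""


class DegenerateDataError(ValueError):
    """Raised when groups are too small or constant for the requested test."""


@dataclass(frozen=True)
class TrendResult:
    """Release-year trend of one (log-transformed) trait."""

    trait_name: str
    slope_per_year: float       # log-units per year
    p_value: float
    percent_change_per_century: float
    model_kind: str             # "mixed_random_intercept" or "ols"
    shapiro_p: float
    slope_se: float = float("nan")
    intercept: float = float("nan")
    n: int = 0

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation CI for the yearly log-scale slope."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (self.slope_per_year - z * self.slope_se,
                self.slope_per_year + z * self.slope_se)

    def __post_init__(self) -> None:
        expected = percent_change_per_century(self.slope_per_year)
        if not math.isclose(self.percent_change_per_century, expected,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("percent change inconsistent with slope")


def percent_change_per_century(slope_per_year: float) -> float:
    """Back-transform a log-scale yearly slope to % change per 100 years."""
    if not math.isfinite(slope_per_year):
        raise ValueError("slope must be finite")
    return (math.exp(100.0 * slope_per_year) - 1.0) * 100.0


def compare_diameter_distributions(
    samples: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Pairwise two-sample KS tests between root-type diameter samples.

    Returns a DataFrame with columns type_a, type_b, ks_statistic, p_value.
    Requires >= 2 root types with >= 5 observations each.
    """
    if len(samples) < 2:
        raise DegenerateDataError("need samples for at least two root types")
    for name, vals in samples.items():
        if len(vals) < 5:
            raise DegenerateDataError(f"root type {name!r}: need >= 5 observations")
    rows = []
    for a, b in combinations(samples, 2):
        res = stats.ks_2samp(np.asarray(samples[a]), np.asarray(samples[b]))
        rows.append({"type_a": a, "type_b": b,
                     "ks_statistic": float(res.statistic),
                     "p_value": float(res.pvalue)})
    return pd.DataFrame(rows)


def _plant_level(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = table[table["trait_name"] == trait]
    if len(sub) == 0:
        raise KeyError(f"trait {trait!r} not present in table")
    # plant averages: one value per plant (pooling duplicate rows)
    g = sub.groupby(["plant_id", "cultivar", "release_year", "season"],
                    as_index=False)["value"].mean()
    return g


def fit_year_trend(
    table: pd.DataFrame,
    trait: str,
    random_season: bool = True,
) -> TrendResult:
    """log(value) ~ release_year, optionally with a season random intercept.

    The mixed model (REML) is used when ``random_season`` and at least two
    seasons are present; it falls back to OLS with a warning when the season
    variance component collapses to ~0 or the fit fails.  The p-value is the
    two-sided test on the year fixed effect.
    """
    g = _plant_level(table, trait)
    bad = g[g["value"] <= 0]
    if len(bad):
        raise TransformationError(
            f"trait {trait!r}: non-positive values for plants "
            f"{bad['plant_id'].tolist()} block the log transform"
        )
    g = g.assign(logv=np.log(g["value"].to_numpy()))
    n_season = g["season"].nunique()

    kind = "ols"
    if random_season and n_season >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm("logv ~ release_year", g, groups=g["season"])
                mf = md.fit(reml=True)
            var_re = float(mf.cov_re.iloc[0, 0])
            if math.isfinite(var_re) and var_re > 1e-12 and \
                    math.isfinite(mf.pvalues["release_year"]):
                kind = "mixed_random_intercept"
                slope = float(mf.params["release_year"])
                intercept = float(mf.params["Intercept"])
                p = float(mf.pvalues["release_year"])
                se = float(mf.bse["release_year"])
                resid = np.asarray(mf.resid)
        except Exception:
            pass
        if kind == "ols":
            warnings.warn(
                f"trait {trait!r}: season variance component ~0 or mixed fit "
                "failed; falling back to OLS", stacklevel=2)
    if kind == "ols":
        mf = smf.ols("logv ~ release_year", g).fit()
        slope = float(mf.params["release_year"])
        intercept = float(mf.params["Intercept"])
        p = float(mf.pvalues["release_year"])
        se = float(mf.bse["release_year"])
        resid = np.asarray(mf.resid)

    shapiro_p = float(stats.shapiro(resid).pvalue) if len(resid) >= 3 else float("nan")
    return TrendResult(
        trait_name=trait,
        slope_per_year=slope,
        p_value=p,
        percent_change_per_century=percent_change_per_century(slope),
        model_kind=kind,
        shapiro_p=shapiro_p,
        slope_se=se,
        intercept=intercept,
        n=len(g),
    )


def cultivar_contrasts(table: pd.DataFrame, trait: str):
    """One-way ANOVA on log values + Tukey HSD pairwise comparisons.

    Returns ``(anova_table, tukey_frame)`` where the ANOVA table is the
    statsmodels type-I table and the Tukey frame has one row per cultivar
    pair with the adjusted p-value.
    """
    g = _plant_level(table, trait)
    if (g["value"] <= 0).any():
        raise TransformationError(f"trait {trait!r}: non-positive values")
    counts = g.groupby("cultivar").size()
    if len(counts) < 2 or (counts < 2).any():
        raise DegenerateDataError("need >= 2 cultivars with >= 2 plants each")
    g = g.assign(logv=np.log(g["value"].to_numpy()))
    fit = smf.ols("logv ~ C(cultivar)", g).fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    with warnings.catch_warnings():
        # degenerate all-equal groups divide by a zero pooled sd
        warnings.simplefilter("ignore", RuntimeWarning)
        tk = pairwise_tukeyhsd(g["logv"].to_numpy(), g["cultivar"].to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return anova, tukey


def crown_tiller_relation(table: pd.DataFrame) -> tuple[float, float, float]:
    """OLS of crown root number on tiller number across plants (pooled).

    Returns (slope, intercept, p_value).  Raises if the traits cannot be
    paired per plant or tiller number is constant.
    """
    crown = _plant_level(table, "crown_root_number").set_index("plant_id")["value"]
    tiller = _plant_level(table, "tiller_number").set_index("plant_id")["value"]
    joined = pd.concat([crown.rename("crown"), tiller.rename("tiller")],
                       axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise DegenerateDataError("need >= 3 plants with both traits")
    if joined["tiller"].nunique() < 2:
        raise DegenerateDataError("tiller number is constant: slope undefined")
    res = stats.linregress(joined["tiller"], joined["crown"])
    return float(res.slope), float(res.intercept), float(res.pvalue)
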