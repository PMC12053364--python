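"""Derived panel quantities and the end-to-end reproduction report.

``derived_trait_changes`` recomputes, from the packaged measured panel, the
headline arithmetic of the breeding analysis: the oldest-to-newest percent
decrease in crown and seminal root number, the absolute lateral-diameter
change per year implied by the -3.5 %/century trend at the oldest cultivar's
diameter, and the panel-wide mean lateral branching density.

``reproduce`` chains the full pipeline on synthetic data (generate ->
chamber fit -> trend statistics) and the growth + hydraulic simulation for
the two calibrated cultivars, and writes a report juxtaposing computed
values with the packaged measured ones.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import params as _p
from .architecture import simulate_growth
from .chamber import filter_outliers, fit_sweep, summarize_by_cultivar
from .hydraulics import krs_trajectory
from .synthetic import generate, table1_defaults
from .traitstats import fit_year_trend, percent_change_per_century

__all__ = [
    "derived_trait_changes",
    "simulate_krs_development",
    "krs_deficit_percent",
    "reproduce",
]

OLDEST = "S. Dickkopf"
NEWEST = "Tommi"


def derived_trait_changes() -> dict[str, float]:
    """Headline derived quantities recomputed from the packaged panel."""
    crown_old = _p.TABLE1["crown_root_number"][OLDEST][0]
    crown_new = _p.TABLE1["crown_root_number"][NEWEST][0]
    sem_old = _p.TABLE1["seminal_root_number"][OLDEST][0]
    sem_new = _p.TABLE1["seminal_root_number"][NEWEST][0]
    # the fitted -3.5 %/century diameter trend expressed as an absolute
    # mm/yr change at the oldest cultivar's diameter (linear spread of the
    # century change over its 100 years)
    pct = _p.TABLE2["lateral_root_diameter"][1]
    d_ref = _p.TABLE1["lateral_root_diameter"][OLDEST][0]
    dens = [_p.TABLE1["branching_density"][c][0] for c in _p.CULTIVARS]
    return {
        "crown_number_decrease_pct": 100.0 * (crown_old - crown_new) / crown_old,
        "seminal_number_decrease_pct": 100.0 * (sem_old - sem_new) / sem_old,
        "lateral_diameter_change_mm_per_yr": d_ref * (pct / 100.0) / 100.0,
        "branching_density_mean_cm": float(np.mean(dens)),
    }


def simulate_krs_development(
    cultivar: str,
    seeds,
    t_end: float = 70.0,
    dt: float = 0.5,
) -> pd.DataFrame:
    """Daily Krs trajectories for one calibrated cultivar, one row per
    (seed, day); columns as in :func:`rhizoflow.hydraulics.krs_trajectory`."""
    cp = _p.cultivar_params(cultivar)
    hyd = _p.cultivar_hydraulics(cultivar)
    frames = []
    for s in seeds:
        traj = simulate_growth(cp, t_end=t_end, dt=dt, seed=int(s))
        df = krs_trajectory(traj, hyd)
        df.insert(0, "seed", int(s))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def krs_deficit_percent(
    old_df: pd.DataFrame, new_df: pd.DataFrame,
    t_min: float = 5.0, t_max: float = 70.0,
) -> float:
    """Time-averaged percent deficit of the modern cultivar's Krs,
    mean over days [t_min, t_max] of (1 - Krs_new / Krs_old) * 100,
    using the seed-averaged daily trajectories."""
    old = old_df.groupby("time")["krs"].mean()
    new = new_df.groupby("time")["krs"].mean()
    times = [t for t in old.index if t_min <= t <= t_max and t in new.index
             and old[t] > 0]
    if not times:
        raise ValueError("no overlapping days with nonzero Krs")
    deficits = [100.0 * (1.0 - new[t] / old[t]) for t in times]
    return float(np.mean(deficits))


def log10_krs_rise(df: pd.DataFrame) -> float:
    """Mean over seeds of log10(Krs at the last day / Krs at the first day
    with nonzero root length)."""
    vals = []
    for _, sub in df.groupby("seed"):
        sub = sub[sub["total_length_m"] > 0].sort_values("time")
        if len(sub) < 2 or sub["krs"].iloc[0] <= 0:
            continue
        vals.append(math.log10(sub["krs"].iloc[-1] / sub["krs"].iloc[0]))
    if not vals:
        raise ValueError("no usable trajectories")
    return float(np.mean(vals))


def reproduce(seed: int = 0, outdir: str | Path = "reproduce_out",
              n_seeds: int = 6, t_end: float = 70.0) -> dict:
    """Run the whole pipeline and write a JSON report to ``outdir``.

    Chains (i) the packaged-panel arithmetic, (ii) synthetic data ->
    pressure-chamber fitting -> trend statistics, and (iii) the 70-day
    growth + Krs simulation for the oldest and most modern cultivars.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed}

    report["derived_trait_changes"] = derived_trait_changes()

    # measurement chain on synthetic data
    bundle = generate(table1_defaults(seed=int(rng.integers(2**31))))
    estimates = filter_outliers([fit_sweep(s) for s in bundle.sweeps])
    summary = summarize_by_cultivar(estimates)
    summary.to_csv(outdir / "chamber_summary.csv", index=False)
    report["chamber"] = {
        row["cultivar"]: {
            "krs_mean": row["krs_mean"],
            "krs_measured": _p.TABLE1["krs"][row["cultivar"]][0],
        }
        for _, row in summary.iterrows()
    }

    # trait trends on synthetic field data
    trends = {}
    for trait in ("crown_root_number", "seminal_root_number", "tiller_number",
                  "lateral_root_diameter"):
        tr = fit_year_trend(bundle.traits, trait, random_season=True)
        trends[trait] = {
            "percent_change_per_century": tr.percent_change_per_century,
            "p_value": tr.p_value,
            "reported_percent_change": _p.TABLE2[trait][1],
        }
    report["trends"] = trends

    # growth + Krs simulation for the two calibrated cultivars
    seeds = [int(s) for s in rng.integers(2**31, size=n_seeds)]
    sims = {}
    traj = {}
    for cult in (OLDEST, NEWEST):
        df = simulate_krs_development(cult, seeds, t_end=t_end)
        traj[cult] = df
        day70 = df[df["time"] == df["time"].max()]
        sims[cult] = {
            "mean_total_length_m_day70": float(day70["total_length_m"].mean()),
            "log10_krs_rise": log10_krs_rise(df),
            "mean_krs_day70": float(day70["krs"].mean()),
        }
        df.to_csv(outdir / f"krs_trajectory_{cult.replace(' ', '_')}.csv",
                  index=False)
    sims["krs_deficit_percent_days5_70"] = krs_deficit_percent(
        traj[OLDEST], traj[NEWEST])
    report["simulation"] = sims

    _plot_trajectories(traj, outdir / "krs_vs_age.png")
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _plot_trajectories(traj: dict, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    for cult, df in traj.items():
        m = df[df["krs"] > 0].groupby("time")["krs"].mean()
        ax.plot(m.index, m.values, label=cult)
    ax.set_yscale("log")
    ax.set_xlabel("plant age (d)")
    ax.set_ylabel(r"$K_{rs}$ (m$^3$ MPa$^{-1}$ s$^{-1}$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
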