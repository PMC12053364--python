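"""Growth-model behaviour: elongation rule, axis demography, branching."""

import math

import numpy as np
import pandas as pd
import pytest

from rhizoflow import params as p
from rhizoflow.architecture import (InvalidParameterError, RootTypeParams,
                                    UnknownCultivarError,
                                    derive_cultivar_params, simulate_growth,
                                    surface_area, total_length)


@pytest.fixture(scope="module")
def dickkopf():
    return p.cultivar_params("S. Dickkopf")


@pytest.fixture(scope="module")
def traj20(dickkopf):
    return simulate_growth(dickkopf, t_end=20.0, dt=0.5, seed=7)


def test_zero_time_gives_empty_system(dickkopf):
    traj = simulate_growth(dickkopf, t_end=0.0, dt=0.5, seed=0)
    assert total_length(traj.final) == 0.0
    assert surface_area(traj.final) == 0.0


def test_invalid_time_step_rejected(dickkopf):
    with pytest.raises(InvalidParameterError):
        simulate_growth(dickkopf, t_end=10.0, dt=0.0, seed=0)
    with pytest.raises(InvalidParameterError):
        simulate_growth(dickkopf, t_end=10.0, dt=1.5, seed=0)
    with pytest.raises(InvalidParameterError):
        simulate_growth(dickkopf, t_end=-1.0, dt=0.5, seed=0)


def test_total_length_monotone_in_time(traj20):
    lengths = [snap.total_length() for snap in traj20]
    assert all(b >= a - 1e-12 for a, b in zip(lengths, lengths[1:]))
    assert lengths[-1] > 0


def test_identical_seeds_give_identical_trees(dickkopf):
    a = simulate_growth(dickkopf, t_end=15.0, dt=0.5, seed=42).final
    b = simulate_growth(dickkopf, t_end=15.0, dt=0.5, seed=42).final
    for attr in ("parent_index", "root_id", "type_code", "length", "radius",
                 "creation_time"):
        assert np.array_equal(getattr(a, attr), getattr(b, attr))
    c = simulate_growth(dickkopf, t_end=15.0, dt=0.5, seed=43).final
    assert not np.array_equal(a.length, c.length)


def test_length_and_area_match_per_segment_oracle(traj20):
    system = traj20.final
    # brute-force summation over the dataclass view
    l_ref = sum(s.length for s in system.segments)
    a_ref = sum(2 * math.pi * s.radius * s.length for s in system.segments)
    assert total_length(system) == pytest.approx(l_ref, rel=1e-12)
    assert surface_area(system) == pytest.approx(a_ref, rel=1e-12)


def test_single_segment_cylinder_area():
    from rhizoflow.architecture import RootSystem

    sys1 = RootSystem(
        np.array([-1]), np.array([0]), np.array([0]),
        np.array([0.1]), np.array([0.00015]), np.array([1.0]), 5.0)
    assert total_length(sys1) == pytest.approx(0.1)
    assert surface_area(sys1) == pytest.approx(2 * math.pi * 0.00015 * 0.1)


def test_axis_lengths_bounded_by_lmax(traj20, dickkopf):
    system = traj20.final
    df = system.to_frame()
    per_root = df.groupby(["root_id", "type"])["length_m"].sum()
    for (rid, rtype), L in per_root.items():
        if rtype == "lateral":
            continue  # lateral Lmax is itself lognormal per root
        lmax_m = dickkopf.type_params(rtype).max_length * 0.01
        assert L <= lmax_m * (1.0 + 1e-9)


def test_axis_counts_match_configuration(dickkopf):
    sem_counts, crown_counts = [], []
    for seed in range(20):
        final = simulate_growth(dickkopf, t_end=70.0, dt=1.0, seed=seed).final
        df = final.to_frame()
        axes = df.groupby("root_id")["type"].first()
        sem_counts.append((axes == "seminal").sum())
        crown_counts.append((axes == "crown").sum())
    n = len(sem_counts)
    sem_mean, sem_se = np.mean(sem_counts), np.std(sem_counts, ddof=1) / n**0.5
    assert abs(sem_mean - dickkopf.seminal_count[0]) <= 2 * sem_se + 0.5
    crown_target = dickkopf.tiller_final_count[0] * dickkopf.crown_roots_per_tiller
    cr_mean, cr_se = np.mean(crown_counts), np.std(crown_counts, ddof=1) / n**0.5
    assert abs(cr_mean - crown_target) <= 2 * cr_se + 0.5


def test_realized_branching_density(dickkopf):
    final = simulate_growth(dickkopf, t_end=60.0, dt=0.5, seed=3).final
    df = final.to_frame()
    tp = dickkopf.type_params("seminal")
    target = 1.0 / (tp.lateral_spacing * 0.01)  # laterals per m
    axes = df[df["type"] != "lateral"]
    lat_first = df[(df["type"] == "lateral")].groupby("root_id").head(1)
    seg_owner = df["root_id"].to_numpy()
    checked = 0
    for rid, grp in axes.groupby("root_id"):
        # attachment positions = cumulative length at the parent segment end
        cum_end = dict(zip(grp["segment_id"], grp["length_m"].cumsum()))
        pos = sorted(cum_end[pid] for pid in lat_first["parent_id"]
                     if seg_owner[pid] == rid)
        if len(pos) < 20:
            continue
        # density on the branched span (count - 1 gaps over the span)
        realized = (len(pos) - 1) / (pos[-1] - pos[0])
        assert realized == pytest.approx(target, rel=0.05)
        checked += 1
    assert checked >= 5


def test_trajectory_snapshots_are_prefixes(traj20):
    snap = traj20.snapshot(10.0)
    final = traj20.final
    n = snap.n_segments
    assert (snap.creation_time <= 10.0).all()
    assert (final.creation_time[n:] > 10.0).all()
    assert np.array_equal(snap.length, final.length[:n])


def _tidy(rows):
    return pd.DataFrame(rows, columns=["plant_id", "cultivar", "release_year",
                                       "season", "trait_name", "value"])


def test_derive_params_from_trait_means():
    rows = []
    for i, (trait, val) in enumerate([
            ("seminal_root_number", 5.9), ("tiller_number", 4.1),
            ("crown_root_number", 11.9), ("branching_density", 1.09),
            ("crown_root_diameter", 0.60), ("seminal_root_diameter", 0.30),
            ("lateral_root_diameter", 0.17)]):
        rows.append((f"P{i}", "Tommi", 2002, "2022-2023", trait, val))
    cp = derive_cultivar_params(_tidy(rows), "Tommi")
    assert cp.seminal_count[0] == pytest.approx(5.9)
    assert cp.tiller_final_count[0] == pytest.approx(4.1)
    assert cp.crown_roots_per_tiller == pytest.approx(11.9 / 4.1)
    assert cp.type_params("seminal").lateral_spacing == pytest.approx(1 / 1.09)
    assert cp.type_params("crown").mean_diameter == pytest.approx(0.60)


def test_crown_per_tiller_ratio_oldest_cultivar():
    cp = p.cultivar_params("S. Dickkopf")
    assert cp.crown_roots_per_tiller == pytest.approx(15.4 / 6.6, rel=1e-9)
    assert cp.seminal_count[0] == pytest.approx(8.2)


def test_derive_params_unknown_cultivar_errors():
    with pytest.raises(UnknownCultivarError):
        derive_cultivar_params(_tidy([]), "Nonexistent")


def test_lateral_spacing_required_for_axile_types():
    with pytest.raises(InvalidParameterError):
        RootTypeParams(type_label="seminal", mean_diameter=0.3,
                       lateral_spacing=None)
    with pytest.raises(InvalidParameterError):
        RootTypeParams(type_label="lateral", mean_diameter=0.17,
                       lateral_spacing=1.0)
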