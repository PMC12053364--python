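"""Synthetic shovelomics tables and pressure-chamber sweeps.

No raw accessions are distributed with the package, so every analysis stage
is exercised on generated data whose statistical structure matches what the
pipeline assumes: plant-level trait values are lognormal around per-cultivar
means (either explicit panel means or a log-linear release-year trend) with
an additive per-season random effect on the log scale; chamber sweeps follow
the applied-pressure protocol with Jv = intercept + Krs * P + noise.  A
configured fraction of sweeps is made deliberately non-linear (saturating,
to be rejected by the linearity QC) and a fraction is made jointly extreme
in Krs, Krs_area and Krs_length (to be caught by the outlier rule).  The
``truth`` record carries every generating parameter so expected estimands
can be recomputed exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import params as _p
from .chamber import PRESSURE_PROTOCOL, PressureSweep

__all__ = [
    "TraitSpec",
    "ChamberSpec",
    "SynthConfig",
    "SynthBundle",
    "generate",
    "table1_defaults",
    "trend_config",
]


class ConfigValidationError(ValueError):
    """Raised with the list of offending fields when a config is invalid."""


@dataclass(frozen=True)
class TraitSpec:
    """Generative spec of one trait.

    Either ``means_by_cultivar`` gives explicit per-cultivar means, or
    ``mean_ref`` (the mean at ``ref_year``) combined with
    ``percent_change_per_century`` defines a log-linear release-year trend.
    ``log_sd`` is the plant-to-plant lognormal sd; ``season_sd`` the sd of
    the additive season effect on the log scale.  ``integer`` rounds values
    to counts >= 0.
    """

    log_sd: float
    season_sd: float = 0.0
    means_by_cultivar: Mapping[str, float] | None = None
    mean_ref: float | None = None
    percent_change_per_century: float = 0.0
    ref_year: int = 1895
    integer: bool = False

    def mean_for(self, cultivar: str, release_year: int) -> float:
        if self.means_by_cultivar is not None:
            return float(self.means_by_cultivar[cultivar])
        slope = math.log(1.0 + self.percent_change_per_century / 100.0) / 100.0
        return float(self.mean_ref * math.exp(slope * (release_year - self.ref_year)))

    def slope_per_year(self) -> float:
        """Planted log-scale yearly slope (trend-specified traits only)."""
        return math.log(1.0 + self.percent_change_per_century / 100.0) / 100.0

    def _invalid(self) -> list[str]:
        bad = []
        if self.log_sd < 0:
            bad.append("log_sd")
        if self.season_sd < 0:
            bad.append("season_sd")
        if self.means_by_cultivar is None and self.mean_ref is None:
            bad.append("mean_ref/means_by_cultivar")
        if self.mean_ref is not None and self.mean_ref <= 0:
            bad.append("mean_ref")
        if self.percent_change_per_century <= -100:
            bad.append("percent_change_per_century")
        return bad


@dataclass(frozen=True)
class ChamberSpec:
    """Generative spec of the pressure-chamber experiment."""

    krs_by_cultivar: Mapping[str, float]        # true mean Krs [m^3 MPa^-1 s^-1]
    area_by_cultivar: Mapping[str, float]       # mean root surface area [m^2]
    length_by_cultivar: Mapping[str, float]     # mean total root length [m]
    plants_per_cultivar: int = 10
    krs_log_sd: float = 0.35        # plant-to-plant lognormal sd of true Krs
    geometry_log_sd: float = 0.20
    flow_noise_sd: float = 1.2e-12  # additive flow noise [m^3 s^-1]
    intercept_range: tuple[float, float] = (0.0, 5e-12)  # [m^3 s^-1]
    fraction_nonlinear: float = 0.0
    fraction_outlier: float = 0.0
    outlier_factor: float = 5.0
    pressures: tuple[float, ...] = PRESSURE_PROTOCOL

    def _invalid(self) -> list[str]:
        bad = []
        if self.plants_per_cultivar < 1:
            bad.append("plants_per_cultivar")
        for name in ("krs_log_sd", "geometry_log_sd", "flow_noise_sd"):
            if getattr(self, name) < 0:
                bad.append(name)
        for name in ("fraction_nonlinear", "fraction_outlier"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                bad.append(name)
        if any(v <= 0 for v in self.krs_by_cultivar.values()):
            bad.append("krs_by_cultivar")
        if len({p for p in self.pressures}) < 3:
            bad.append("pressures")
        return bad


@dataclass(frozen=True)
class SynthConfig:
    """Full generator configuration (cultivar panel + trait and chamber specs)."""

    cultivars: tuple[tuple[str, int], ...]
    traits: Mapping[str, TraitSpec]
    chamber: ChamberSpec | None
    plants_per_cultivar_per_season: int = 15
    seasons: tuple[str, ...] = ("2022-2023", "2023-2024")
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.plants_per_cultivar_per_season < 1:
            bad.append("plants_per_cultivar_per_season")
        if len(self.cultivars) < 1:
            bad.append("cultivars")
        for name, spec in self.traits.items():
            bad += [f"traits[{name}].{b}" for b in spec._invalid()]
        if self.chamber is not None:
            bad += [f"chamber.{b}" for b in self.chamber._invalid()]
        if bad:
            raise ConfigValidationError(f"invalid config fields: {bad}")


@dataclass
class SynthBundle:
    """Generated data plus the exact generating parameters."""

    traits: pd.DataFrame
    sweeps: list[PressureSweep]
    truth: dict


def _exact_count(frac: float, n: int) -> int:
    return int(round(frac * n))


def generate(config: SynthConfig, seed: int | None = None) -> SynthBundle:
    """Draw a reproducible :class:`SynthBundle` from ``config``.

    ``seed`` overrides ``config.seed`` when given; identical seeds give
    identical bundles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # --- trait table ------------------------------------------------------
    rows = []
    season_effects: dict[tuple[str, str], float] = {}
    for trait, spec in config.traits.items():
        for season in config.seasons:
            eff = rng.normal(0.0, spec.season_sd) if spec.season_sd > 0 else 0.0
            season_effects[(trait, season)] = float(eff)
    plant_serial = 0
    plant_ids: dict[tuple[str, str], list[str]] = {}
    for cult, year in config.cultivars:
        for season in config.seasons:
            ids = []
            for _ in range(config.plants_per_cultivar_per_season):
                ids.append(f"P{plant_serial:05d}")
                plant_serial += 1
            plant_ids[(cult, season)] = ids
    for trait, spec in config.traits.items():
        for cult, year in config.cultivars:
            mu = spec.mean_for(cult, year)
            for season in config.seasons:
                eff = season_effects[(trait, season)]
                for pid in plant_ids[(cult, season)]:
                    noise = rng.normal(0.0, spec.log_sd) if spec.log_sd > 0 else 0.0
                    v = mu * math.exp(eff + noise)
                    if spec.integer:
                        v = max(0.0, float(round(v)))
                    rows.append({"plant_id": pid, "cultivar": cult,
                                 "release_year": year, "season": season,
                                 "trait_name": trait, "value": v})
    traits = pd.DataFrame(rows,
                          columns=["plant_id", "cultivar", "release_year",
                                   "season", "trait_name", "value"])

    # --- chamber sweeps ---------------------------------------------------
    sweeps: list[PressureSweep] = []
    chamber_truth: dict = {}
    if config.chamber is not None:
        ch = config.chamber
        serial = 0
        for cult, year in config.cultivars:
            n = ch.plants_per_cultivar
            n_nl = _exact_count(ch.fraction_nonlinear, n)
            n_out = _exact_count(ch.fraction_outlier, n)
            roles = ["nonlinear"] * n_nl + ["outlier"] * n_out
            roles += ["normal"] * (n - len(roles))
            rng.shuffle(roles)
            mu_k = ch.krs_by_cultivar[cult]
            mu_a = ch.area_by_cultivar[cult]
            mu_l = ch.length_by_cultivar[cult]
            sig_k = math.sqrt(math.log(1.0 + ch.krs_log_sd ** 2))
            sig_g = math.sqrt(math.log(1.0 + ch.geometry_log_sd ** 2))
            for role in roles:
                pid = f"C{serial:05d}"
                serial += 1
                if role == "outlier":
                    # jointly extreme in all three measures: Krs pinned at a
                    # multiple of the cultivar mean, geometry at the mean so
                    # the normalised values shift too
                    true_k = mu_k * ch.outlier_factor
                    area, length = mu_a, mu_l
                else:
                    true_k = mu_k * rng.lognormal(-0.5 * sig_k ** 2, sig_k)
                    area = mu_a * rng.lognormal(-0.5 * sig_g ** 2, sig_g)
                    length = mu_l * rng.lognormal(-0.5 * sig_g ** 2, sig_g)
                b = float(rng.uniform(*ch.intercept_range))
                readings = []
                for P in ch.pressures:
                    if role == "nonlinear":
                        # saturating Jv(P): strongly concave on the protocol
                        jv = b + true_k * 0.45 * math.tanh(P / 0.09)
                    else:
                        jv = b + true_k * P
                    jv += rng.normal(0.0, ch.flow_noise_sd)
                    readings.append((P, jv))
                sweeps.append(PressureSweep(
                    plant_id=pid, cultivar=cult, release_year=year,
                    readings=tuple(readings),
                    root_surface_area=area, total_root_length=length,
                ))
                chamber_truth[pid] = {"cultivar": cult, "role": role,
                                      "true_krs": float(true_k),
                                      "area_m2": float(area),
                                      "length_m": float(length),
                                      "intercept": b}

    truth = {
        "seed": config.seed if seed is None else seed,
        "season_effects": {f"{t}|{s}": e for (t, s), e in season_effects.items()},
        "trait_specs": {
            name: {
                "slope_per_year": (spec.slope_per_year()
                                   if spec.means_by_cultivar is None else None),
                "percent_change_per_century": spec.percent_change_per_century,
                "log_sd": spec.log_sd, "season_sd": spec.season_sd,
                "means": {c: spec.mean_for(c, y) for c, y in config.cultivars},
            }
            for name, spec in config.traits.items()
        },
        "chamber": chamber_truth,
        "chamber_spec": None if config.chamber is None else {
            "krs_by_cultivar": dict(config.chamber.krs_by_cultivar),
            "fraction_nonlinear": config.chamber.fraction_nonlinear,
            "fraction_outlier": config.chamber.fraction_outlier,
        },
    }
    return SynthBundle(traits=traits, sweeps=sweeps, truth=truth)


def table1_defaults(
    fraction_nonlinear: float = 0.1,
    fraction_outlier: float = 0.1,
    seed: int = 0,
) -> SynthConfig:
    """Packaged config whose cultivar means equal the measured panel values.

    Trait means/SEs follow the measured per-cultivar table; plant-level sds
    are recovered from the tabulated standard errors at the midpoint of the
    stated n ranges (29.5 plants for field traits, 10 for chamber traits).
    """
    n_field = 0.5 * sum(_p.FIELD_N_RANGE)
    n_chamber = 0.5 * sum(_p.CHAMBER_N_RANGE)
    cultivars = tuple((c, _p.RELEASE_YEARS[c]) for c in _p.CULTIVARS)

    traits: dict[str, TraitSpec] = {}
    field_traits = ["crown_root_diameter", "seminal_root_diameter",
                    "lateral_root_diameter", "crown_root_number",
                    "seminal_root_number", "tiller_number", "branching_density"]
    for trait in field_traits:
        means = {c: _p.TABLE1[trait][c][0] for c in _p.CULTIVARS}
        # pooled plant-level CV from SE * sqrt(n) / mean, averaged over panel
        cvs = [_p.TABLE1[trait][c][1] * math.sqrt(n_field) / _p.TABLE1[trait][c][0]
               for c in _p.CULTIVARS]
        cv = float(np.mean(cvs))
        traits[trait] = TraitSpec(
            log_sd=math.sqrt(math.log(1.0 + cv * cv)),
            season_sd=0.05,
            means_by_cultivar=means,
            integer=trait.endswith("_number"),
        )
    chamber = ChamberSpec(
        krs_by_cultivar={c: _p.TABLE1["krs"][c][0] for c in _p.CULTIVARS},
        area_by_cultivar={c: _p.TABLE1["root_surface_area"][c][0] * 1e-4
                          for c in _p.CULTIVARS},
        length_by_cultivar={c: _p.TABLE1["total_root_length"][c][0] * 1e-2
                            for c in _p.CULTIVARS},
        plants_per_cultivar=int(n_chamber),
        krs_log_sd=_chamber_log_sd(),
        fraction_nonlinear=fraction_nonlinear,
        fraction_outlier=fraction_outlier,
    )
    return SynthConfig(cultivars=cultivars, traits=traits, chamber=chamber,
                       plants_per_cultivar_per_season=15, seed=seed)


def _chamber_log_sd() -> float:
    """Plant-level lognormal sd of Krs implied by the tabulated SEs."""
    n = 0.5 * sum(_p.CHAMBER_N_RANGE)
    cvs = [_p.TABLE1["krs"][c][1] * math.sqrt(n) / _p.TABLE1["krs"][c][0]
           for c in _p.CULTIVARS]
    cv = float(np.mean(cvs))
    return math.sqrt(math.log(1.0 + cv * cv))


def trend_config(
    trait: str = "crown_root_number",
    percent_change_per_century: float = -20.0,
    mean_ref: float = 15.0,
    log_sd: float = 0.25,
    season_sd: float = 0.08,
    plants: int = 15,
    integer: bool = False,
    seed: int = 0,
) -> SynthConfig:
    """Trend-specified panel for parameter-recovery simulations.

    Unlike :func:`table1_defaults` the cultivar means lie exactly on the
    planted log-linear release-year trend, so the trend estimator's CI
    coverage can be assessed against a known truth.
    """
    cultivars = tuple((c, _p.RELEASE_YEARS[c]) for c in _p.CULTIVARS)
    spec = TraitSpec(
        log_sd=log_sd, season_sd=season_sd, mean_ref=mean_ref,
        percent_change_per_century=percent_change_per_century,
        ref_year=min(_p.RELEASE_YEARS.values()), integer=integer,
    )
    return SynthConfig(cultivars=cultivars, traits={trait: spec}, chamber=None,
                       plants_per_cultivar_per_season=plants, seed=seed)
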