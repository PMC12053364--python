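"""Packaged cultivar panel, measured trait tables and calibrated defaults.

The panel covers six German winter-wheat cultivars released between 1895 and
2002.  ``TABLE1`` holds the measured plant-level trait means and standard
errors (field shovelomics at the end of tillering, n = 27-32 plants per
cultivar; hydroponic pressure-chamber traits at 10-12 days, n = 8-12) and
``TABLE2`` the release-year trend statistics (percent change per century on
the log scale).

Growth constants that shovelomics cannot deliver (axis maximum lengths,
elongation rates, branching zones) and the age-dependent kr/kx knots are
packaged calibrated defaults: scripts/calibrate.py tunes them jointly so
that (i) simulated Krs at 10-12 days matches the measured cultivar means,
(ii) the 70-day Krs trajectory spans about three orders of magnitude, and
(iii) day-70 total root length exceeds 120 m (S. Dickkopf) and 63 m (Tommi).
"""

from __future__ import annotations

from types import MappingProxyType

from .architecture import CultivarParams, RootTypeParams
from .hydraulics import HydraulicParams, PiecewiseLinearFunction

__all__ = [
    "CULTIVARS",
    "RELEASE_YEARS",
    "TABLE1",
    "TABLE2",
    "FIELD_N_RANGE",
    "CHAMBER_N_RANGE",
    "base_cultivar_params",
    "cultivar_params",
    "default_hydraulics",
    "cultivar_hydraulics",
    "HYDRAULIC_SCALE",
]

#: cultivar name -> release year, oldest to most modern
RELEASE_YEARS = {
    "S. Dickkopf": 1895,
    "SG v. Stocken": 1920,
    "Heines II": 1940,
    "Jubilar": 1961,
    "Okapi": 1978,
    "Tommi": 2002,
}
CULTIVARS = tuple(RELEASE_YEARS)

FIELD_N_RANGE = (27, 32)    # plants per cultivar, shovelomics traits
CHAMBER_N_RANGE = (8, 12)   # plants per cultivar, pressure-chamber traits

#: measured trait means and standard errors per cultivar: trait -> cultivar
#: -> (mean, se).  Diameters mm; counts dimensionless; branching density
#: cm^-1; surface area cm^2; length cm; krs m^3 MPa^-1 s^-1; krs_area
#: m MPa^-1 s^-1; krs_length m^3 MPa^-1 s^-1 m^-1.
TABLE1 = {
    "crown_root_diameter": {
        "S. Dickkopf": (0.62, 0.009), "SG v. Stocken": (0.58, 0.008),
        "Heines II": (0.61, 0.009), "Jubilar": (0.61, 0.007),
        "Okapi": (0.63, 0.011), "Tommi": (0.60, 0.010),
    },
    "seminal_root_diameter": {
        "S. Dickkopf": (0.30, 0.008), "SG v. Stocken": (0.30, 0.008),
        "Heines II": (0.30, 0.009), "Jubilar": (0.28, 0.005),
        "Okapi": (0.32, 0.009), "Tommi": (0.30, 0.007),
    },
    "lateral_root_diameter": {
        "S. Dickkopf": (0.18, 0.001), "SG v. Stocken": (0.17, 0.002),
        "Heines II": (0.18, 0.002), "Jubilar": (0.17, 0.001),
        "Okapi": (0.17, 0.002), "Tommi": (0.17, 0.002),
    },
    "crown_root_number": {
        "S. Dickkopf": (15.4, 0.8), "SG v. Stocken": (12.8, 0.7),
        "Heines II": (13.1, 0.6), "Jubilar": (13.0, 0.7),
        "Okapi": (12.6, 0.6), "Tommi": (11.9, 0.5),
    },
    "seminal_root_number": {
        "S. Dickkopf": (8.2, 0.5), "SG v. Stocken": (6.2, 0.3),
        "Heines II": (5.6, 0.2), "Jubilar": (5.1, 0.2),
        "Okapi": (6.2, 0.3), "Tommi": (5.9, 0.3),
    },
    "tiller_number": {
        "S. Dickkopf": (6.6, 0.2), "SG v. Stocken": (4.8, 0.1),
        "Heines II": (4.2, 0.1), "Jubilar": (5.6, 0.2),
        "Okapi": (4.9, 0.2), "Tommi": (4.1, 0.2),
    },
    "branching_density": {
        "S. Dickkopf": (1.10, 0.05), "SG v. Stocken": (1.16, 0.15),
        "Heines II": (1.10, 0.05), "Jubilar": (0.98, 0.06),
        "Okapi": (0.91, 0.04), "Tommi": (1.09, 0.06),
    },
    "root_surface_area": {
        "S. Dickkopf": (7.8, 0.5), "SG v. Stocken": (7.6, 0.9),
        "Heines II": (7.4, 0.5), "Jubilar": (7.4, 0.9),
        "Okapi": (7.8, 0.6), "Tommi": (6.4, 0.6),
    },
    "total_root_length": {
        "S. Dickkopf": (71.5, 4.7), "SG v. Stocken": (69.2, 9.1),
        "Heines II": (69.5, 6.2), "Jubilar": (66.4, 8.3),
        "Okapi": (70.4, 6.0), "Tommi": (57.9, 6.1),
    },
    "krs": {
        "S. Dickkopf": (1.3e-10, 0.2e-10), "SG v. Stocken": (1.1e-10, 0.2e-10),
        "Heines II": (1.3e-10, 0.2e-10), "Jubilar": (1.2e-10, 0.2e-10),
        "Okapi": (0.9e-10, 0.1e-10), "Tommi": (0.7e-10, 0.1e-10),
    },
    "krs_area": {
        "S. Dickkopf": (1.7e-7, 0.2e-7), "SG v. Stocken": (1.5e-7, 0.2e-7),
        "Heines II": (1.7e-7, 0.2e-7), "Jubilar": (1.6e-7, 0.1e-7),
        "Okapi": (1.2e-7, 0.1e-7), "Tommi": (1.1e-7, 0.1e-7),
    },
    "krs_length": {
        "S. Dickkopf": (1.9e-10, 0.2e-10), "SG v. Stocken": (1.6e-10, 0.1e-10),
        "Heines II": (1.8e-10, 0.3e-10), "Jubilar": (1.8e-10, 0.1e-10),
        "Okapi": (1.3e-10, 0.2e-10), "Tommi": (1.2e-10, 0.1e-10),
    },
}

#: release-year trend: trait -> (p_label, percent change per 100 years)
TABLE2 = {
    "crown_root_diameter": ("0.74", +0.6),
    "seminal_root_diameter": ("0.92", +0.3),
    "lateral_root_diameter": ("<0.05", -3.5),
    "crown_root_number": ("<0.001", -19.4),
    "seminal_root_number": ("<0.001", -23.4),
    "tiller_number": ("<0.001", -31.3),
    "branching_density": ("0.27", -9.2),
    "root_surface_area": ("0.22", -13.7),
    "total_root_length": ("0.19", -15.1),
    "krs": ("<0.01", -51.8),
    "krs_area": ("<0.01", -38.1),
    "krs_length": ("<0.01", -36.8),
}

# ---------------------------------------------------------------------------
# calibrated growth defaults (see scripts/calibrate.py)
# ---------------------------------------------------------------------------

#: per-type growth constants shared by all cultivars unless overridden below
GROWTH_DEFAULTS = {
    "seminal": dict(max_length=150.0, initial_elongation_rate=3.0,
                    apical_unbranched_zone=8.0, basal_unbranched_zone=1.0,
                    emergence_delay=1.0, diameter_cv=0.10),
    "crown": dict(max_length=130.0, initial_elongation_rate=3.2,
                  apical_unbranched_zone=8.0, basal_unbranched_zone=1.0,
                  emergence_delay=0.0, diameter_cv=0.10),
    "lateral": dict(max_length=7.0, initial_elongation_rate=1.5,
                    apical_unbranched_zone=0.0, basal_unbranched_zone=0.0,
                    emergence_delay=2.0, diameter_cv=0.10, max_length_cv=0.3),
}

#: per-cultivar multiplier on axis maximum lengths (calibrated; the modern
#: cultivar builds a markedly smaller root system)
AXIS_LENGTH_SCALE = {"S. Dickkopf": 1.0, "Tommi": 0.72}

#: crown-root cohorts span a common tillering window for all cultivars
#: (sampling happened simultaneously at the end of tillering), so the
#: per-cultivar phyllochron is the window divided by the final tiller count
CROWN_EMERGENCE_START = 10.0  # day of first crown cohort
TILLERING_END = 65.0          # day the last cohort can appear


def _count_sd(trait: str, cultivar: str) -> float:
    """Plant-level sd from the tabulated SE at the midpoint field n."""
    n_mid = 0.5 * (FIELD_N_RANGE[0] + FIELD_N_RANGE[1])
    return TABLE1[trait][cultivar][1] * n_mid ** 0.5


def base_cultivar_params(name: str, release_year: int | None = None) -> CultivarParams:
    """CultivarParams with packaged growth constants and neutral trait means.

    Used as the template that :func:`rhizoflow.architecture.derive_cultivar_params`
    fills with measured trait means; counts default to the panel means when
    the cultivar is in the packaged panel.
    """
    year = RELEASE_YEARS.get(name, release_year)
    if year is None:
        raise KeyError(f"unknown cultivar {name!r} and no release_year given")
    scale = AXIS_LENGTH_SCALE.get(name, 1.0)
    in_panel = name in RELEASE_YEARS

    def tp(t: str, diameter: float, spacing: float | None) -> RootTypeParams:
        kw = dict(GROWTH_DEFAULTS[t])
        kw["max_length"] = kw["max_length"] * scale
        return RootTypeParams(type_label=t, mean_diameter=diameter,
                              lateral_spacing=spacing, **kw)

    if in_panel:
        d_sem = TABLE1["seminal_root_diameter"][name][0]
        d_cro = TABLE1["crown_root_diameter"][name][0]
        d_lat = TABLE1["lateral_root_diameter"][name][0]
        spacing = 1.0 / TABLE1["branching_density"][name][0]
        sem_n = TABLE1["seminal_root_number"][name]
        til_n = TABLE1["tiller_number"][name]
        crown_mean = TABLE1["crown_root_number"][name][0]
        return CultivarParams(
            name=name,
            release_year=year,
            seminal_count=(sem_n[0], _count_sd("seminal_root_number", name)),
            tiller_final_count=(til_n[0], _count_sd("tiller_number", name)),
            phyllochron=(TILLERING_END - CROWN_EMERGENCE_START) / til_n[0],
            crown_roots_per_tiller=crown_mean / til_n[0],
            crown_emergence_start=CROWN_EMERGENCE_START,
            crown_emergence_end=TILLERING_END,
            root_type_params=MappingProxyType({
                "seminal": tp("seminal", d_sem, spacing),
                "crown": tp("crown", d_cro, spacing),
                "lateral": tp("lateral", d_lat, None),
            }),
        )
    # generic wheat defaults for cultivars outside the packaged panel
    return CultivarParams(
        name=name, release_year=year,
        seminal_count=(6.0, 1.0), tiller_final_count=(5.0, 1.0),
        phyllochron=(TILLERING_END - CROWN_EMERGENCE_START) / 5.0,
        crown_roots_per_tiller=2.5,
        crown_emergence_start=CROWN_EMERGENCE_START,
        crown_emergence_end=TILLERING_END,
        root_type_params=MappingProxyType({
            "seminal": tp("seminal", 0.30, 0.91),
            "crown": tp("crown", 0.60, 0.91),
            "lateral": tp("lateral", 0.17, None),
        }),
    )


def cultivar_params(name: str) -> CultivarParams:
    """Packaged architecture parameters for a panel cultivar."""
    if name not in RELEASE_YEARS:
        raise KeyError(f"cultivar {name!r} is not in the packaged panel {CULTIVARS}")
    return base_cultivar_params(name)


# ---------------------------------------------------------------------------
# calibrated hydraulic defaults
# ---------------------------------------------------------------------------

def default_hydraulics() -> HydraulicParams:
    """Packaged age-dependent kr/kx knots per root type (unscaled base).

    Shapes follow the canonical wheat pattern: radial conductivity peaks in
    young tissue and declines as apoplastic barriers mature; axial
    conductance rises steeply as xylem vessels mature, more for axile roots
    than for laterals.  Absolute levels are calibrated (see module
    docstring); per-cultivar levels come from :data:`HYDRAULIC_SCALE`.
    """
    P = PiecewiseLinearFunction.from_knots
    kr_axile = P([(0.0, 4.0e-8), (5.0, 2.6e-7), (12.0, 1.8e-7),
                  (30.0, 6.0e-8), (60.0, 2.5e-8)])
    kr_lateral = P([(0.0, 8.0e-8), (3.0, 5.0e-7), (10.0, 3.5e-7),
                    (25.0, 1.2e-7), (50.0, 6.0e-8)])
    kx_axile = P([(0.0, 8.0e-13), (10.0, 4.0e-12), (25.0, 1.0e-11),
                  (50.0, 1.8e-11)])
    kx_lateral = P([(0.0, 6.0e-14), (8.0, 3.0e-13), (25.0, 6.0e-13)])
    return HydraulicParams(
        kr_by_type={"seminal": kr_axile, "crown": kr_axile, "lateral": kr_lateral},
        kx_by_type={"seminal": kx_axile, "crown": kx_axile, "lateral": kx_lateral},
    )


#: per-cultivar joint kr&kx multiplier calibrated so that the simulated mean
#: Krs over days 10-12 equals the measured cultivar mean (scaling kr and kx
#: by the same factor scales Krs by exactly that factor).
HYDRAULIC_SCALE = {"S. Dickkopf": 0.495, "Tommi": 0.337}


def cultivar_hydraulics(name: str) -> HydraulicParams:
    """Calibrated hydraulic parametrisation for a panel cultivar."""
    try:
        s = HYDRAULIC_SCALE[name]
    except KeyError:
        raise KeyError(
            f"no hydraulic calibration for {name!r}; available: {sorted(HYDRAULIC_SCALE)}"
        ) from None
    return default_hydraulics().scaled(s, s)
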