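"""Tabular and configuration file formats.

CSV dialect: UTF-8, comma separated, '.' decimal, mandatory header row, SI
units in column names.  Writers use a fixed float format so that
write -> read -> write is byte-identical.

Cultivar architecture parameters use a small XML dialect (one ``<root>``
block per root type); hydraulic parameters use YAML with per-type
``[age_day, value]`` knot lists for kr and kx.
"""

from __future__ import annotations

from pathlib import Path
from types import MappingProxyType

import numpy as np
import pandas as pd
import yaml
from lxml import etree

from .architecture import ROOT_TYPES, CultivarParams, RootSystem, RootTypeParams
from .chamber import KrsEstimate, PressureSweep
from .hydraulics import HydraulicParams, PiecewiseLinearFunction

__all__ = [
    "write_segments_csv", "read_segments_csv",
    "write_traits_csv", "read_traits_csv",
    "write_sweeps_csv", "read_sweeps",
    "write_estimates_csv",
    "write_cultivar_xml", "read_cultivar_xml",
    "write_hydraulics_yaml", "read_hydraulics_yaml",
]

_FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Raised on malformed input files, naming the file and offending part."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


# --- segment edge lists ----------------------------------------------------

SEGMENT_COLUMNS = ("segment_id", "parent_id", "root_id", "type",
                   "length_m", "radius_m", "creation_day")


def write_segments_csv(system: RootSystem, path) -> None:
    system.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_segments_csv(path) -> RootSystem:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _require_columns(df, SEGMENT_COLUMNS, path)
    bad = ~df["type"].isin(ROOT_TYPES)
    if bad.any():
        raise ParseError(
            f"{path}: unknown root type(s) {sorted(df.loc[bad, 'type'].unique())} "
            f"at line(s) {list(df.index[bad] + 2)}"
        )
    return RootSystem.from_frame(df)


# --- trait tables ----------------------------------------------------------

TRAIT_COLUMNS = ("plant_id", "cultivar", "release_year", "season",
                 "trait_name", "value")


def write_traits_csv(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_traits_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _require_columns(df, TRAIT_COLUMNS, path)
    return df


# --- pressure sweeps -------------------------------------------------------

SWEEP_COLUMNS = ("plant_id", "cultivar", "release_year",
                 "pressure_MPa", "flow_m3_s")
GEOMETRY_COLUMNS = ("plant_id", "area_m2", "length_m")


def write_sweeps_csv(sweeps, sweeps_path, geometry_path) -> None:
    srows, grows = [], []
    for s in sweeps:
        for P, jv in s.readings:
            srows.append({"plant_id": s.plant_id, "cultivar": s.cultivar,
                          "release_year": s.release_year,
                          "pressure_MPa": P, "flow_m3_s": jv})
        grows.append({"plant_id": s.plant_id, "area_m2": s.root_surface_area,
                      "length_m": s.total_root_length})
    pd.DataFrame(srows).to_csv(sweeps_path, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(grows).to_csv(geometry_path, index=False, float_format=_FLOAT_FMT)


def read_sweeps(sweeps_path, geometry_path) -> list[PressureSweep]:
    try:
        sdf = pd.read_csv(sweeps_path)
        gdf = pd.read_csv(geometry_path)
    except Exception as exc:
        raise ParseError(f"{sweeps_path}/{geometry_path}: {exc}") from exc
    _require_columns(sdf, SWEEP_COLUMNS, sweeps_path)
    _require_columns(gdf, GEOMETRY_COLUMNS, geometry_path)
    geom = gdf.set_index("plant_id")
    sweeps = []
    for pid, grp in sdf.groupby("plant_id", sort=False):
        if pid not in geom.index:
            raise ParseError(f"{geometry_path}: no geometry row for plant {pid!r}")
        g = geom.loc[pid]
        sweeps.append(PressureSweep(
            plant_id=str(pid),
            cultivar=str(grp["cultivar"].iloc[0]),
            release_year=int(grp["release_year"].iloc[0]),
            readings=tuple(zip(grp["pressure_MPa"].astype(float),
                               grp["flow_m3_s"].astype(float))),
            root_surface_area=float(g["area_m2"]),
            total_root_length=float(g["length_m"]),
        ))
    return sweeps


def write_estimates_csv(estimates, path) -> None:
    rows = [{
        "plant_id": e.plant_id, "cultivar": e.cultivar,
        "release_year": e.release_year, "krs_m3_MPa_s": e.krs,
        "intercept_m3_s": e.intercept, "r_squared": e.r_squared,
        "krs_area_m_MPa_s": e.krs_area, "krs_length_m3_MPa_s_m": e.krs_length,
        "qc_pass": e.qc_pass, "outlier": e.outlier,
    } for e in estimates]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


# --- cultivar architecture XML --------------------------------------------

_PLANT_FIELDS = ("phyllochron", "crown_roots_per_tiller",
                 "crown_emergence_start", "seminal_stagger")
_TYPE_FIELDS = ("mean_diameter", "diameter_cv", "max_length",
                "initial_elongation_rate", "apical_unbranched_zone",
                "basal_unbranched_zone", "lateral_spacing",
                "emergence_delay", "max_length_cv")


def write_cultivar_xml(params: CultivarParams, path) -> None:
    plant = etree.Element("plant", name=params.name,
                          release_year=str(params.release_year))
    for label, pair in (("seminal_count", params.seminal_count),
                        ("tiller_final_count", params.tiller_final_count)):
        etree.SubElement(plant, "param", name=label,
                         mean=_FLOAT_FMT % pair[0], sd=_FLOAT_FMT % pair[1])
    for f in _PLANT_FIELDS:
        etree.SubElement(plant, "param", name=f,
                         value=_FLOAT_FMT % getattr(params, f))
    for t in ROOT_TYPES:
        tp = params.type_params(t)
        el = etree.SubElement(plant, "root", type=t)
        for f in _TYPE_FIELDS:
            v = getattr(tp, f)
            if v is None:
                continue
            etree.SubElement(el, "param", name=f, value=_FLOAT_FMT % v)
    etree.ElementTree(plant).write(str(path), xml_declaration=True,
                                   encoding="UTF-8", pretty_print=True)


def read_cultivar_xml(path) -> CultivarParams:
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if root.tag != "plant":
        raise ParseError(f"{path}: expected <plant> root element, got <{root.tag}>")
    pairs: dict[str, tuple[float, float]] = {}
    scalars: dict[str, float] = {}
    for el in root.findall("param"):
        name = el.get("name")
        if el.get("mean") is not None:
            pairs[name] = (float(el.get("mean")), float(el.get("sd", "0")))
        else:
            scalars[name] = float(el.get("value"))
    rtp: dict[str, RootTypeParams] = {}
    for el in root.findall("root"):
        t = el.get("type")
        if t not in ROOT_TYPES:
            raise ParseError(f"{path}: unknown root type {t!r} (line {el.sourceline})")
        kw = {p.get("name"): float(p.get("value")) for p in el.findall("param")}
        rtp[t] = RootTypeParams(type_label=t, **kw)
    try:
        return CultivarParams(
            name=root.get("name"),
            release_year=int(root.get("release_year")),
            seminal_count=pairs["seminal_count"],
            tiller_final_count=pairs["tiller_final_count"],
            phyllochron=scalars["phyllochron"],
            crown_roots_per_tiller=scalars["crown_roots_per_tiller"],
            crown_emergence_start=scalars.get("crown_emergence_start", 10.0),
            seminal_stagger=scalars.get("seminal_stagger", 0.5),
            root_type_params=MappingProxyType(rtp),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing parameter {exc}") from exc


# --- hydraulic parameter YAML ---------------------------------------------

def write_hydraulics_yaml(hydraulics: HydraulicParams, path) -> None:
    doc = {
        "kr": {t: [[a, v] for a, v in zip(f.ages, f.values)]
               for t, f in hydraulics.kr_by_type.items()},
        "kx": {t: [[a, v] for a, v in zip(f.ages, f.values)]
               for t, f in hydraulics.kx_by_type.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_hydraulics_yaml(path) -> HydraulicParams:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        kr = {t: PiecewiseLinearFunction.from_knots(k) for t, k in doc["kr"].items()}
        kx = {t: PiecewiseLinearFunction.from_knots(k) for t, k in doc["kx"].items()}
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: expected kr/kx per-type knot lists") from exc
    return HydraulicParams(kr_by_type=kr, kx_by_type=kx)
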