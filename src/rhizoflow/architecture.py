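"""Stochastic simulator of winter-wheat root-system development.

The root system is represented as a forest of cylindrical segments attached
at the plant collar.  Three root types are simulated:

* **seminal** roots — embryo-derived axes, emerging staggered during the
  first days after sowing;
* **crown** roots — shoot-borne axes emerging in cohorts tied to tiller
  appearance (one cohort per phyllochron, ``crown_roots_per_tiller`` roots
  each);
* **lateral** roots — first-order branch roots initiated behind the apical
  unbranched zone of their parent axis at a regular spacing
  (= 1 / branching density).

Every axis elongates following the negative-exponential rule

    L(t) = Lmax * (1 - exp(-r0 * t / Lmax))

with ``r0`` the initial elongation rate and ``Lmax`` the asymptotic length,
so that length is monotone, saturating and never exceeds ``Lmax``.
Elongation during a time step either extends the axis with a new segment or
is carried over until the accumulated increment exceeds a minimum segment
length.  Geometry (3D coordinates) is deliberately not simulated: the
hydraulic conductance of the system depends only on topology, segment
lengths, radii and ages.

Units: user-facing growth parameters are in cm / mm / days as customary in
root phenotyping; segment lengths and radii are stored in SI metres; time in
days.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROOT_TYPES",
    "RootTypeParams",
    "CultivarParams",
    "RootSegment",
    "RootSystem",
    "GrowthTrajectory",
    "simulate_growth",
    "total_length",
    "surface_area",
    "derive_cultivar_params",
]

ROOT_TYPES = ("seminal", "crown", "lateral")
TYPE_CODE = {t: i for i, t in enumerate(ROOT_TYPES)}

_CM = 0.01  # m per cm
_MM = 1e-3  # m per mm

#: minimum emitted segment length [m]; smaller growth increments are carried
#: over to the next step so the segment count stays bounded.
MIN_SEGMENT_LENGTH = 5e-4

#: relative distance to Lmax below which an axis stops being updated
_DONE_FRACTION = 1e-4


class InvalidParameterError(ValueError):
    """Raised when simulation parameters violate their invariants."""


class ConfigurationError(ValueError):
    """Raised when a required root-type parametrisation is missing."""


@dataclass(frozen=True)
class RootTypeParams:
    """Growth parameters of one root type.

    Parameters use field-customary units: diameters in mm, lengths/zones in
    cm, elongation rate in cm day^-1, delays in days.  ``lateral_spacing``
    is the inter-branch distance on the parent (1 / branching density) and
    must be absent (None) for laterals, which do not branch further.
    """

    type_label: str
    mean_diameter: float            # mm
    diameter_cv: float = 0.1        # lognormal CV of individual diameters
    max_length: float = 100.0       # cm
    initial_elongation_rate: float = 2.0  # cm / day
    apical_unbranched_zone: float = 8.0   # cm
    basal_unbranched_zone: float = 1.0    # cm
    lateral_spacing: float | None = None  # cm; parents only
    emergence_delay: float = 0.0    # day
    max_length_cv: float = 0.0      # lognormal CV of per-root Lmax

    def __post_init__(self) -> None:
        if self.type_label not in ROOT_TYPES:
            raise InvalidParameterError(f"unknown root type {self.type_label!r}")
        if self.mean_diameter <= 0:
            raise InvalidParameterError("mean_diameter must be > 0")
        if self.max_length <= 0:
            raise InvalidParameterError("max_length must be > 0")
        if self.initial_elongation_rate <= 0:
            raise InvalidParameterError("initial_elongation_rate must be > 0")
        if self.type_label == "lateral":
            if self.lateral_spacing is not None:
                raise InvalidParameterError("laterals do not carry a lateral_spacing")
        else:
            if self.lateral_spacing is None or self.lateral_spacing <= 0:
                raise InvalidParameterError(
                    f"{self.type_label} roots need lateral_spacing > 0"
                )
        if self.diameter_cv < 0 or self.max_length_cv < 0:
            raise InvalidParameterError("coefficients of variation must be >= 0")
        if self.emergence_delay < 0:
            raise InvalidParameterError("emergence_delay must be >= 0")


@dataclass(frozen=True)
class CultivarParams:
    """Whole-plant architecture parameters of one cultivar.

    ``seminal_count`` and ``tiller_final_count`` are (mean, sd) pairs of the
    plant-to-plant distributions; counts are resampled per simulated plant.
    Crown roots emerge in cohorts: the first at ``crown_emergence_start``
    days (the "tiller 0" cohort of the main stem) and one additional cohort
    per ``phyllochron`` until ``tiller_final_count`` cohorts have appeared,
    each contributing ``crown_roots_per_tiller`` roots on average.
    """

    name: str
    release_year: int
    seminal_count: tuple[float, float]
    tiller_final_count: tuple[float, float]
    phyllochron: float              # days between tiller (crown cohort) events
    crown_roots_per_tiller: float
    root_type_params: Mapping[str, RootTypeParams]
    crown_emergence_start: float = 10.0  # day of first crown cohort
    crown_emergence_end: float = math.inf  # cohorts later than this are clamped
    seminal_stagger: float = 0.5    # days between successive seminal emergences

    def __post_init__(self) -> None:
        if self.seminal_count[0] < 1:
            raise InvalidParameterError("seminal_count mean must be >= 1")
        if self.crown_roots_per_tiller <= 0:
            raise InvalidParameterError("crown_roots_per_tiller must be > 0")
        if self.phyllochron <= 0:
            raise InvalidParameterError("phyllochron must be > 0")
        missing = [t for t in ROOT_TYPES if t not in self.root_type_params]
        if missing:
            raise ConfigurationError(f"missing root-type parameters: {missing}")

    def type_params(self, root_type: str) -> RootTypeParams:
        try:
            return self.root_type_params[root_type]
        except KeyError as exc:  # pragma: no cover - guarded in __post_init__
            raise ConfigurationError(f"no parameters for root type {root_type!r}") from exc


@dataclass(frozen=True)
class RootSegment:
    """One cylindrical root segment (SI units: m, days)."""

    segment_id: int
    parent_id: int | None
    root_id: int
    root_type: str
    length: float
    radius: float
    creation_time: float


class RootSystem:
    """Snapshot of a root system as columnar segment arrays.

    Segments are stored in creation order, which is also a topological order
    (every parent precedes its children).  ``parent_index`` is -1 for
    segments attached directly at the collar.
    """

    def __init__(
        self,
        parent_index: np.ndarray,
        root_id: np.ndarray,
        type_code: np.ndarray,
        length: np.ndarray,
        radius: np.ndarray,
        creation_time: np.ndarray,
        simulation_time: float,
        seed: int | None = None,
    ) -> None:
        n = len(length)
        for arr in (parent_index, root_id, type_code, radius, creation_time):
            if len(arr) != n:
                raise InvalidParameterError("segment arrays must share one length")
        self.parent_index = np.asarray(parent_index, dtype=np.int64)
        self.root_id = np.asarray(root_id, dtype=np.int64)
        self.type_code = np.asarray(type_code, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.radius = np.asarray(radius, dtype=float)
        self.creation_time = np.asarray(creation_time, dtype=float)
        self.simulation_time = float(simulation_time)
        self.seed = seed
        self._validate()

    def _validate(self) -> None:
        if self.n_segments == 0:
            return
        if (self.length <= 0).any() or (self.radius <= 0).any():
            raise InvalidParameterError("segment lengths and radii must be > 0")
        if (self.creation_time < 0).any():
            raise InvalidParameterError("creation times must be >= 0")
        if (self.parent_index >= np.arange(self.n_segments)).any():
            raise InvalidParameterError(
                "segments must be topologically ordered (parent before child)"
            )
        par = self.parent_index
        has_par = par >= 0
        if (self.creation_time[has_par] < self.creation_time[par[has_par]]).any():
            raise InvalidParameterError("a segment cannot predate its parent")

    @property
    def n_segments(self) -> int:
        return len(self.length)

    @property
    def segments(self) -> list[RootSegment]:
        out = []
        for i in range(self.n_segments):
            p = int(self.parent_index[i])
            out.append(
                RootSegment(
                    segment_id=i,
                    parent_id=None if p < 0 else p,
                    root_id=int(self.root_id[i]),
                    root_type=ROOT_TYPES[int(self.type_code[i])],
                    length=float(self.length[i]),
                    radius=float(self.radius[i]),
                    creation_time=float(self.creation_time[i]),
                )
            )
        return out

    def total_length(self) -> float:
        """Summed segment length [m]."""
        return float(self.length.sum())

    def surface_area(self) -> float:
        """Summed lateral cylinder surface, sum(2*pi*r*l) [m^2]."""
        return float((2.0 * np.pi * self.radius * self.length).sum())

    def to_frame(self) -> pd.DataFrame:
        """Edge-list representation (segment_id, parent_id, ...)."""
        return pd.DataFrame(
            {
                "segment_id": np.arange(self.n_segments, dtype=np.int64),
                "parent_id": self.parent_index,
                "root_id": self.root_id,
                "type": [ROOT_TYPES[c] for c in self.type_code],
                "length_m": self.length,
                "radius_m": self.radius,
                "creation_day": self.creation_time,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, simulation_time: float | None = None,
                   seed: int | None = None) -> "RootSystem":
        type_code = np.array([TYPE_CODE[t] for t in frame["type"]], dtype=np.int64)
        tmax = float(frame["creation_day"].max()) if len(frame) else 0.0
        return cls(
            parent_index=frame["parent_id"].to_numpy(),
            root_id=frame["root_id"].to_numpy(),
            type_code=type_code,
            length=frame["length_m"].to_numpy(),
            radius=frame["radius_m"].to_numpy(),
            creation_time=frame["creation_day"].to_numpy(),
            simulation_time=tmax if simulation_time is None else simulation_time,
            seed=seed,
        )

    @classmethod
    def empty(cls, simulation_time: float = 0.0, seed: int | None = None) -> "RootSystem":
        z = np.empty(0)
        zi = np.empty(0, dtype=np.int64)
        return cls(zi, zi, zi, z, z, z, simulation_time, seed)


def total_length(system: RootSystem) -> float:
    """Total root length [m] of a snapshot."""
    return system.total_length()


def surface_area(system: RootSystem) -> float:
    """Total root surface area [m^2] of a snapshot."""
    return system.surface_area()


def _axis_length(lmax: float, r0: float, age: float) -> float:
    """Negative-exponential axis length [same units as lmax], age in days."""
    if age <= 0.0:
        return 0.0
    return lmax * (1.0 - math.exp(-r0 * age / lmax))


class _Axis:
    """Mutable per-root growth state (internal)."""

    __slots__ = (
        "root_id", "type_code", "t_emerge", "lmax", "r0", "radius",
        "spacing", "auz", "buz", "next_branch", "analytic_len",
        "pending", "tip_seg", "cum_len", "seg_idx", "done",
    )

    def __init__(self, root_id, type_code, t_emerge, lmax, r0, radius,
                 spacing, auz, buz, first_offset):
        self.root_id = root_id
        self.type_code = type_code
        self.t_emerge = t_emerge
        self.lmax = lmax          # m
        self.r0 = r0              # m / day
        self.radius = radius      # m
        self.spacing = spacing    # m or None
        self.auz = auz            # m
        self.buz = buz            # m
        self.next_branch = None if spacing is None else buz + first_offset
        self.analytic_len = 0.0
        self.pending = 0.0
        self.tip_seg = -1         # global index of current tip segment
        self.cum_len = []         # cumulative length at each own segment end
        self.seg_idx = []         # global indices of own segments
        self.done = False


class GrowthTrajectory:
    """Result of :func:`simulate_growth`: a lazily sliced time series.

    Segments never change once created (elongation only appends new ones),
    so the full end-state table plus creation times defines every
    intermediate snapshot.  ``snapshot(t)`` returns the prefix of segments
    with ``creation_time <= t``.
    """

    def __init__(self, final: RootSystem, times: np.ndarray, seed: int) -> None:
        self._final = final
        self.times = np.asarray(times, dtype=float)
        self.seed = seed

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[RootSystem]:
        for t in self.times:
            yield self.snapshot(t)

    @property
    def final(self) -> RootSystem:
        return self._final

    def snapshot(self, t: float) -> RootSystem:
        f = self._final
        n = int(np.searchsorted(f.creation_time, t, side="right"))
        return RootSystem(
            f.parent_index[:n], f.root_id[:n], f.type_code[:n],
            f.length[:n], f.radius[:n], f.creation_time[:n],
            simulation_time=float(t), seed=self.seed,
        )


def _sample_lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Mean-preserving lognormal draw with coefficient of variation ``cv``."""
    if cv <= 0:
        return mean
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(mean * rng.lognormal(-0.5 * sigma * sigma, sigma))


def simulate_growth(
    params: CultivarParams,
    t_end: float,
    dt: float = 0.5,
    seed: int = 0,
    snapshot_every: float = 1.0,
) -> GrowthTrajectory:
    """Simulate root-system development from sowing (day 0) to ``t_end``.

    Returns a :class:`GrowthTrajectory` with snapshots at multiples of
    ``snapshot_every`` (plus ``t_end``).  Identical arguments give
    bit-identical trajectories.
    """
    if t_end < 0:
        raise InvalidParameterError("t_end must be >= 0")
    if not (0 < dt <= 1):
        raise InvalidParameterError("dt must satisfy 0 < dt <= 1")
    if t_end == 0:
        return GrowthTrajectory(RootSystem.empty(0.0, seed), np.array([0.0]), seed)

    rng = np.random.default_rng(seed)

    sem = params.type_params("seminal")
    cro = params.type_params("crown")
    lat = params.type_params("lateral")

    axes: list[_Axis] = []
    next_root_id = 0

    def _new_axis(tp: RootTypeParams, t_emerge: float) -> _Axis:
        nonlocal next_root_id
        lmax = _sample_lognormal(rng, tp.max_length * _CM, tp.max_length_cv)
        radius = 0.5 * _sample_lognormal(rng, tp.mean_diameter * _MM, tp.diameter_cv)
        spacing = None if tp.lateral_spacing is None else tp.lateral_spacing * _CM
        offset = 0.0 if spacing is None else spacing * float(rng.uniform())
        ax = _Axis(
            root_id=next_root_id,
            type_code=TYPE_CODE[tp.type_label],
            t_emerge=t_emerge,
            lmax=lmax,
            r0=tp.initial_elongation_rate * _CM,
            radius=radius,
            spacing=spacing,
            auz=tp.apical_unbranched_zone * _CM,
            buz=tp.basal_unbranched_zone * _CM,
            first_offset=offset,
        )
        next_root_id += 1
        return ax

    # --- plan axile roots -------------------------------------------------
    n_sem = max(1, int(round(rng.normal(*params.seminal_count))))
    for i in range(n_sem):
        axes.append(_new_axis(sem, sem.emergence_delay + i * params.seminal_stagger))

    n_till = max(0, int(round(rng.normal(*params.tiller_final_count))))
    cpt = params.crown_roots_per_tiller
    for k in range(n_till):
        cohort = int(round(cpt * (k + 1))) - int(round(cpt * k))
        t_cohort = min(params.crown_emergence_start + k * params.phyllochron,
                       params.crown_emergence_end)
        for _ in range(cohort):
            axes.append(_new_axis(cro, t_cohort + cro.emergence_delay))

    # --- grow -------------------------------------------------------------
    seg_parent: list[int] = []
    seg_root: list[int] = []
    seg_type: list[int] = []
    seg_len: list[float] = []
    seg_rad: list[float] = []
    seg_time: list[float] = []

    n_steps = int(math.ceil(t_end / dt - 1e-9))
    for step in range(n_steps):
        t0 = step * dt
        t1 = min((step + 1) * dt, t_end)
        new_laterals: list[_Axis] = []
        for ax in axes:
            if ax.done or t1 <= ax.t_emerge:
                continue
            age1 = t1 - ax.t_emerge
            new_len = _axis_length(ax.lmax, ax.r0, age1)
            inc = new_len - ax.analytic_len
            ax.analytic_len = new_len
            ax.pending += inc
            if ax.pending >= MIN_SEGMENT_LENGTH:
                idx = len(seg_len)
                seg_parent.append(ax.tip_seg)
                seg_root.append(ax.root_id)
                seg_type.append(ax.type_code)
                seg_len.append(ax.pending)
                seg_rad.append(ax.radius)
                seg_time.append(t1)
                base = ax.cum_len[-1] if ax.cum_len else 0.0
                ax.cum_len.append(base + ax.pending)
                ax.seg_idx.append(idx)
                ax.tip_seg = idx
                ax.pending = 0.0
            if new_len >= ax.lmax * (1.0 - _DONE_FRACTION):
                ax.done = True
            # lateral initiation behind the apical unbranched zone
            if ax.spacing is not None:
                while ax.cum_len and ax.next_branch + ax.auz <= ax.analytic_len:
                    pos = ax.next_branch
                    if pos >= ax.cum_len[-1]:
                        break
                    j = bisect_left(ax.cum_len, pos)
                    parent_seg = ax.seg_idx[min(j, len(ax.seg_idx) - 1)]
                    child = _new_axis(lat, t1 + lat.emergence_delay)
                    child.tip_seg = parent_seg
                    new_laterals.append(child)
                    ax.next_branch += ax.spacing
        axes.extend(new_laterals)

    final = RootSystem(
        np.array(seg_parent, dtype=np.int64),
        np.array(seg_root, dtype=np.int64),
        np.array(seg_type, dtype=np.int64),
        np.array(seg_len, dtype=float),
        np.array(seg_rad, dtype=float),
        np.array(seg_time, dtype=float),
        simulation_time=t_end,
        seed=seed,
    )
    times = np.arange(0.0, t_end + 1e-9, snapshot_every)
    if times[-1] < t_end - 1e-9:
        times = np.append(times, t_end)
    return GrowthTrajectory(final, times, seed)


class UnknownCultivarError(LookupError):
    """Raised when a trait table holds no rows for the requested cultivar."""


def derive_cultivar_params(
    traits: pd.DataFrame,
    cultivar: str,
    base: CultivarParams | None = None,
) -> CultivarParams:
    """Build :class:`CultivarParams` from plant-level trait means.

    ``traits`` is a tidy table with columns plant_id, cultivar, release_year,
    season, trait_name, value.  Counts, per-type diameters and the lateral
    spacing (1 / branching density) come from the cultivar's trait means;
    growth constants not measurable by shovelomics (max lengths, elongation
    rates, zones) are taken from ``base`` (packaged wheat defaults if None).
    """
    from . import params as _p  # local import to avoid a cycle

    sub = traits[traits["cultivar"] == cultivar]
    if len(sub) == 0:
        raise UnknownCultivarError(f"no trait rows for cultivar {cultivar!r}")
    if base is None:
        base = _p.base_cultivar_params(cultivar, sub["release_year"].iloc[0])

    def mean_of(trait: str, default: float) -> float:
        vals = sub.loc[sub["trait_name"] == trait, "value"]
        return float(vals.mean()) if len(vals) else default

    sem_n = mean_of("seminal_root_number", base.seminal_count[0])
    tiller_n = mean_of("tiller_number", base.tiller_final_count[0])
    crown_n = mean_of("crown_root_number",
                      base.crown_roots_per_tiller * base.tiller_final_count[0])
    density = mean_of("branching_density", None if base is None else
                      1.0 / base.type_params("seminal").lateral_spacing)
    spacing = 1.0 / density

    rtp = {}
    for t in ROOT_TYPES:
        tp = base.type_params(t)
        diam = mean_of(f"{t}_root_diameter", tp.mean_diameter)
        rtp[t] = replace(
            tp,
            mean_diameter=diam,
            lateral_spacing=None if t == "lateral" else spacing,
        )
    return replace(
        base,
        seminal_count=(sem_n, base.seminal_count[1]),
        tiller_final_count=(tiller_n, base.tiller_final_count[1]),
        crown_roots_per_tiller=crown_n / tiller_n,
        root_type_params=rtp,
    )
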