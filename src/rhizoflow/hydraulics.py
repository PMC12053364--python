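"""Whole-root-system hydraulic conductance (Krs) from segment-scale properties.

The root system is treated as a network of conductances between the xylem
and a uniform external medium (the hydroponic solution).  Each cylindrical
segment has

* a radial conductivity ``kr`` [m MPa^-1 s^-1] — water permeability of the
  root surface per unit area, and
* an axial conductance ``kx`` [m^4 MPa^-1 s^-1] — xylem flow per unit axial
  water-potential gradient,

both age-dependent through per-root-type piecewise-linear functions.  The
equivalent conductance of a segment of length ``l`` and radius ``r`` that
feeds a distal subtree of conductance ``K_distal`` follows the exact
transmission-line solution of flow with distributed radial entry:

    tau   = sqrt(2*pi*r*kr / kx)        [1/m]
    kappa = sqrt(2*pi*r*kr * kx)        [m^3 MPa^-1 s^-1]
    K     = kappa * (K_distal + kappa*tanh(tau*l))
                  / (kappa + K_distal*tanh(tau*l))

Child conductances add in parallel (plain summation) at branch points and at
the collar, which is an ideal node.  Krs is the collar flux per unit
medium-collar potential difference.

An independent brute-force oracle (:func:`network_oracle`) discretises every
segment into an explicit resistor chain and solves the sparse linear system;
it is used to verify the analytic fold, never to replace it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .architecture import ROOT_TYPES, TYPE_CODE, GrowthTrajectory, RootSystem

__all__ = [
    "PiecewiseLinearFunction",
    "HydraulicParams",
    "KrsResult",
    "property_at",
    "segment_conductance",
    "compute_krs",
    "network_oracle",
    "krs_trajectory",
    "sensitivity_sweep",
]


class HydraulicInputError(ValueError):
    """Raised on invalid hydraulic inputs (negative age, bad geometry, ...)."""


class SingularNetworkError(RuntimeError):
    """Raised when the resistor network has no path to the external medium."""


@dataclass(frozen=True)
class PiecewiseLinearFunction:
    """Age -> value map, linear between knots, clamped outside them."""

    ages: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ages) < 1 or len(self.ages) != len(self.values):
            raise HydraulicInputError("need >= 1 (age, value) knot")
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])):
            raise HydraulicInputError("knot ages must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise HydraulicInputError("knot values must be >= 0")

    @classmethod
    def from_knots(cls, knots: Iterable[tuple[float, float]]) -> "PiecewiseLinearFunction":
        pairs = tuple((float(a), float(v)) for a, v in knots)
        return cls(tuple(a for a, _ in pairs), tuple(v for _, v in pairs))

    def __call__(self, age):
        age_arr = np.asarray(age, dtype=float)
        if (age_arr < 0).any():
            raise HydraulicInputError("age must be >= 0")
        out = np.interp(age_arr, self.ages, self.values)
        return float(out) if np.isscalar(age) or age_arr.ndim == 0 else out

    def scaled(self, factor: float) -> "PiecewiseLinearFunction":
        if factor <= 0:
            raise HydraulicInputError("scale factor must be > 0")
        return PiecewiseLinearFunction(self.ages, tuple(v * factor for v in self.values))


def property_at(f: PiecewiseLinearFunction, age: float) -> float:
    """Evaluate a piecewise-linear conductivity at ``age`` days."""
    return f(age)


@dataclass(frozen=True)
class HydraulicParams:
    """Per-root-type age-dependent kr [m MPa^-1 s^-1] and kx [m^4 MPa^-1 s^-1]."""

    kr_by_type: Mapping[str, PiecewiseLinearFunction]
    kx_by_type: Mapping[str, PiecewiseLinearFunction]

    def __post_init__(self) -> None:
        for t in ROOT_TYPES:
            if t not in self.kr_by_type or t not in self.kx_by_type:
                raise HydraulicInputError(f"missing kr/kx for root type {t!r}")

    def scaled(self, kr_factor: float = 1.0, kx_factor: float = 1.0) -> "HydraulicParams":
        """Globally rescale kr and/or kx (used by the sensitivity sweep and
        by the per-cultivar calibration; scaling both by c scales Krs by c)."""
        return HydraulicParams(
            {t: f.scaled(kr_factor) for t, f in self.kr_by_type.items()},
            {t: f.scaled(kx_factor) for t, f in self.kx_by_type.items()},
        )


@dataclass(frozen=True)
class KrsResult:
    """Krs and its size normalisations for one snapshot."""

    krs: float          # m^3 MPa^-1 s^-1
    krs_area: float     # m MPa^-1 s^-1   (krs / total surface area)
    krs_length: float   # m^3 MPa^-1 s^-1 m^-1 (krs / total length)
    time: float         # day
    total_length: float = 0.0  # m
    surface_area: float = 0.0  # m^2


_TWO_PI = 2.0 * math.pi


def segment_conductance(l: float, r: float, kr: float, kx: float,
                        K_distal: float = 0.0) -> float:
    """Equivalent conductance [m^3 MPa^-1 s^-1] of one segment + distal subtree.

    ``l`` may be 0 (transparent segment).  ``kr = 0`` degenerates to the pure
    axial series combination of kx/l with ``K_distal``.
    """
    if l < 0 or r <= 0 or kx <= 0 or kr < 0 or K_distal < 0:
        raise HydraulicInputError("need l >= 0, r > 0, kx > 0, kr >= 0, K_distal >= 0")
    if l == 0.0:
        return K_distal
    if kr == 0.0:
        if K_distal == 0.0:
            return 0.0
        return 1.0 / (l / kx + 1.0 / K_distal)
    tau = math.sqrt(_TWO_PI * r * kr / kx)
    kappa = math.sqrt(_TWO_PI * r * kr * kx)
    th = math.tanh(tau * l)
    return kappa * (K_distal + kappa * th) / (kappa + K_distal * th)


def _fold_py(parent, length, radius, krv, kxv):
    n = len(length)
    acc = np.zeros(n)
    collar = 0.0
    for i in range(n - 1, -1, -1):
        l = length[i]
        kr = krv[i]
        kx = kxv[i]
        Kd = acc[i]
        if kr <= 0.0:
            K = 0.0 if Kd <= 0.0 else 1.0 / (l / kx + 1.0 / Kd)
        else:
            tau = math.sqrt(_TWO_PI * radius[i] * kr / kx)
            kappa = math.sqrt(_TWO_PI * radius[i] * kr * kx)
            th = math.tanh(tau * l)
            K = kappa * (Kd + kappa * th) / (kappa + Kd * th)
        p = parent[i]
        if p < 0:
            collar += K
        else:
            acc[p] += K
    return collar


try:  # compiled fold: the hot loop of daily Krs over ~1e5 segments
    from numba import njit as _njit

    _fold = _njit(cache=True)(_fold_py)
except Exception:  # pragma: no cover - numba is an optional accelerator
    _fold = _fold_py


def _segment_properties(system: RootSystem, hydraulics: HydraulicParams, t: float):
    """Ages and per-segment kr/kx for segments existing at time ``t``."""
    n = int(np.searchsorted(system.creation_time, t + 1e-12, side="right")) \
        if _is_time_sorted(system) else None
    if n is None:
        mask = system.creation_time <= t + 1e-12
        idx = np.nonzero(mask)[0]
    else:
        idx = np.arange(n)
    age = t - system.creation_time[idx]
    kr = np.empty(len(idx))
    kx = np.empty(len(idx))
    codes = system.type_code[idx]
    for tname, code in TYPE_CODE.items():
        m = codes == code
        if m.any():
            kr[m] = hydraulics.kr_by_type[tname](age[m])
            kx[m] = hydraulics.kx_by_type[tname](age[m])
    return idx, kr, kx


def _is_time_sorted(system: RootSystem) -> bool:
    ct = system.creation_time
    return len(ct) < 2 or bool((np.diff(ct) >= 0).all())


def compute_krs(
    system: RootSystem,
    hydraulics: HydraulicParams,
    t: float | None = None,
    age_resolution: float | None = None,
) -> KrsResult:
    """Krs of a snapshot at time ``t`` (default: the snapshot's own time).

    Each segment carries a single creation time, so ages are uniform within
    a segment and the exact transmission-line fold applies per segment
    without further splitting; ``age_resolution`` is accepted for interface
    compatibility and only relevant for externally built systems whose
    discretisation is coarser than the growth model's (those are used as-is).
    Segments created after ``t`` are excluded; an empty system yields zeros.
    """
    if t is None:
        t = system.simulation_time
    if system.n_segments == 0:
        return KrsResult(0.0, 0.0, 0.0, t)
    if t < float(system.creation_time.min()):
        return KrsResult(0.0, 0.0, 0.0, t)
    idx, kr, kx = _segment_properties(system, hydraulics, t)
    if len(idx) == 0:
        return KrsResult(0.0, 0.0, 0.0, t)
    sub_parent = system.parent_index[idx]
    if len(idx) and idx[-1] != len(idx) - 1:  # non-contiguous selection: remap
        lookup = -np.ones(system.n_segments, dtype=np.int64)
        lookup[idx] = np.arange(len(idx))
        sub_parent = np.where(sub_parent >= 0, lookup[sub_parent], -1)
    length = system.length[idx]
    radius = system.radius[idx]
    krs = float(_fold(sub_parent, length, radius, kr, kx))
    tot_l = float(length.sum())
    area = float((_TWO_PI * radius * length).sum())
    return KrsResult(
        krs=krs,
        krs_area=krs / area if area > 0 else 0.0,
        krs_length=krs / tot_l if tot_l > 0 else 0.0,
        time=t,
        total_length=tot_l,
        surface_area=area,
    )


def network_oracle(
    system: RootSystem,
    hydraulics: HydraulicParams,
    t: float | None = None,
    nodes_per_segment: int = 1000,
) -> float:
    """Brute-force Krs: explicit resistor network solved sparsely.

    Every segment becomes ``nodes_per_segment`` axial sub-resistors
    (kx / dl each) with radial conductances kr*2*pi*r*dl tied from the xylem
    nodes to the external medium (trapezoidal end weights).  The collar is
    held at unit potential against the medium; the returned collar flux is
    the conductance.  Independent of the analytic fold by construction.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.linalg import spsolve

    if nodes_per_segment < 2:
        raise HydraulicInputError("nodes_per_segment must be >= 2")
    if t is None:
        t = system.simulation_time
    if system.n_segments == 0:
        return 0.0
    idx, kr_seg, kx_seg = _segment_properties(system, hydraulics, t)
    if len(idx) == 0:
        return 0.0
    nseg = len(idx)
    N = nodes_per_segment
    # node 0 = collar (fixed at potential 1); nodes 1.. are unknowns
    n_nodes = 1 + nseg * N
    pos_of = {int(g): k for k, g in enumerate(idx)}  # global seg -> local

    rows, cols, vals = [], [], []   # off-diagonal (negative) entries
    diag = np.zeros(n_nodes)
    rhs = np.zeros(n_nodes)

    def add_edge(a: int, b: int, g: float) -> None:
        diag[a] += g
        diag[b] += g
        rows.append(a); cols.append(b); vals.append(-g)
        rows.append(b); cols.append(a); vals.append(-g)

    radial_at_node = np.zeros(n_nodes)  # conductance to medium (potential 0)

    for k in range(nseg):
        gseg = int(idx[k])
        l = system.length[gseg]
        r = system.radius[gseg]
        dl = l / N
        g_ax = kx_seg[k] / dl
        g_rad = kr_seg[k] * _TWO_PI * r * dl
        p = int(system.parent_index[gseg])
        prox = 0 if p < 0 else 1 + pos_of[p] * N + (N - 1)
        first = 1 + k * N
        nodes = [prox] + list(range(first, first + N))
        for a, b in zip(nodes[:-1], nodes[1:]):
            add_edge(a, b, g_ax)
        # trapezoid: half radial weight at the end nodes
        radial_at_node[nodes[0]] += 0.5 * g_rad
        radial_at_node[nodes[-1]] += 0.5 * g_rad
        for nd in nodes[1:-1]:
            radial_at_node[nd] += g_rad

    diag += radial_at_node  # ties to the medium at potential 0

    # Dirichlet condition at collar: move its column to the RHS
    import warnings as _warnings

    from scipy import sparse
    from scipy.sparse.linalg import MatrixRankWarning

    A = coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()
    A = A + sparse.diags(diag)
    u = np.zeros(n_nodes)
    unknown = np.arange(1, n_nodes)
    A_uu = A[unknown][:, unknown]
    b = -A[unknown][:, [0]].toarray().ravel() * 1.0  # collar potential = 1
    u[0] = 1.0
    with _warnings.catch_warnings():
        _warnings.simplefilter("error", MatrixRankWarning)
        try:
            u[unknown] = spsolve(A_uu.tocsc(), b)
        except MatrixRankWarning as exc:
            raise SingularNetworkError(
                "resistor network is singular (disconnected from collar "
                "and medium)") from exc
    if not np.isfinite(u).all():
        raise SingularNetworkError("network solve produced non-finite potentials")
    # collar flux: axial edges incident to node 0 plus its radial tie
    row0 = A[[0]].toarray().ravel()
    flux = radial_at_node[0] * (u[0] - 0.0)
    off = row0.copy()
    off[0] = 0.0
    flux += float(np.sum(-off * (u[0] - u)))
    return float(flux)


def krs_trajectory(
    trajectory: GrowthTrajectory | Sequence[RootSystem],
    hydraulics: HydraulicParams,
) -> pd.DataFrame:
    """One :class:`KrsResult` row per snapshot (columns: time, krs,
    krs_area, krs_length, total_length_m, surface_area_m2)."""
    rows = []
    for snap in trajectory:
        res = compute_krs(snap, hydraulics)
        rows.append(
            {
                "time": res.time,
                "krs": res.krs,
                "krs_area": res.krs_area,
                "krs_length": res.krs_length,
                "total_length_m": res.total_length,
                "surface_area_m2": res.surface_area,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_sweep(
    system: RootSystem,
    hydraulics: HydraulicParams,
    factors: Sequence[float],
    target: str = "both",
    t: float | None = None,
) -> pd.DataFrame:
    """Krs under global rescaling of kr, kx or both by each factor."""
    if target not in ("kr", "kx", "both"):
        raise HydraulicInputError("target must be 'kr', 'kx' or 'both'")
    rows = []
    for f in factors:
        if f <= 0:
            raise HydraulicInputError("factors must be > 0")
        kr_f = f if target in ("kr", "both") else 1.0
        kx_f = f if target in ("kx", "both") else 1.0
        res = compute_krs(system, hydraulics.scaled(kr_f, kx_f), t=t)
        rows.append({"factor": f, "target": target, "krs": res.krs,
                     "krs_area": res.krs_area, "krs_length": res.krs_length})
    return pd.DataFrame(rows)
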