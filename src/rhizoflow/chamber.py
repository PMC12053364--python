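"""Pressure-chamber estimation of whole-root-system conductance (Krs).

A de-topped root system is pressurised in nutrient solution and the sap flow
Jv [m^3 s^-1] exuding at the cut is recorded at several applied pressures P
[MPa] (protocol sequence 0.16, 0.24, 0.1, 0.32, 0.24 MPa after a
pre-pressurisation phase).  Under steady state Jv is linear in P and the
slope of the ordinary least-squares fit Jv = a + Krs * P is the conductance;
the intercept is left free because pre-pressurisation can leave a nonzero
flow offset.  Sweeps whose Jv(P) relation is not linear (r^2 below a
threshold, default 0.95) or whose slope is non-positive fail QC.

Per cultivar, a sample is flagged as an outlier when it falls outside
[Q1 - 1.5 IQR, Q3 + 1.5 IQR] for *all three* of Krs, Krs_area and
Krs_length, and an iterative two-sided Grubbs test on Krs confirms it.
Flags are annotations; no reading is ever mutated or dropped silently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PressureSweep",
    "KrsEstimate",
    "PRESSURE_PROTOCOL",
    "fit_sweep",
    "grubbs_outlier_indices",
    "filter_outliers",
    "summarize_by_cultivar",
]

#: applied-pressure protocol [MPa]; the repeated 0.24 MPa reading enters the
#: fit as a separate point.
PRESSURE_PROTOCOL = (0.16, 0.24, 0.1, 0.32, 0.24)


class InsufficientDataError(ValueError):
    """Raised when a sweep has fewer than three distinct pressures."""


@dataclass(frozen=True)
class PressureSweep:
    """Ordered (pressure [MPa], flow [m^3 s^-1]) record of one plant."""

    plant_id: str
    cultivar: str
    release_year: int
    readings: tuple[tuple[float, float], ...]
    root_surface_area: float    # m^2
    total_root_length: float    # m

    def __post_init__(self) -> None:
        if self.root_surface_area <= 0 or self.total_root_length <= 0:
            raise ValueError("root surface area and length must be > 0")
        if any(p <= 0 for p, _ in self.readings):
            raise ValueError("pressures must be > 0")
        if len({p for p, _ in self.readings}) < 3:
            raise InsufficientDataError(
                f"sweep {self.plant_id}: need >= 3 distinct pressures"
            )

    @property
    def pressures(self) -> np.ndarray:
        return np.array([p for p, _ in self.readings])

    @property
    def flows(self) -> np.ndarray:
        return np.array([q for _, q in self.readings])


@dataclass(frozen=True)
class KrsEstimate:
    """Slope-based Krs estimate with QC and outlier annotations."""

    plant_id: str
    cultivar: str
    release_year: int
    krs: float          # m^3 MPa^-1 s^-1
    intercept: float    # m^3 s^-1
    r_squared: float
    krs_area: float     # m MPa^-1 s^-1
    krs_length: float   # m^3 MPa^-1 s^-1 m^-1
    qc_pass: bool
    outlier: bool = False


def fit_sweep(sweep: PressureSweep, r2_threshold: float = 0.95) -> KrsEstimate:
    """OLS of flow on pressure; Krs = slope, intercept free.

    ``qc_pass`` requires r^2 >= ``r2_threshold`` and a positive slope.
    """
    P = sweep.pressures
    Jv = sweep.flows
    res = stats.linregress(P, Jv)
    slope = float(res.slope)
    r2 = float(res.rvalue ** 2)
    return KrsEstimate(
        plant_id=sweep.plant_id,
        cultivar=sweep.cultivar,
        release_year=sweep.release_year,
        krs=slope,
        intercept=float(res.intercept),
        r_squared=r2,
        krs_area=slope / sweep.root_surface_area,
        krs_length=slope / sweep.total_root_length,
        qc_pass=bool(r2 >= r2_threshold and slope > 0),
    )


def grubbs_outlier_indices(
    values: Sequence[float], alpha: float = 0.05, max_iter: int = 2
) -> set[int]:
    """Indices flagged by the iterative two-sided single-outlier Grubbs test.

    At each iteration the most extreme remaining value is tested with
    G = max|x - mean| / sd against the t-based critical value
    G_crit = (N-1)/sqrt(N) * sqrt(t^2 / (N - 2 + t^2)) with
    t = t_{alpha/(2N), N-2}; at most one value is removed per iteration.
    """
    x = np.asarray(values, dtype=float)
    active = list(range(len(x)))
    flagged: set[int] = set()
    for _ in range(max_iter):
        n = len(active)
        if n < 3:
            break
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        G = dev[j] / sd
        t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
        g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        if G > g_crit:
            flagged.add(active.pop(j))
        else:
            break
    return flagged


def _iqr_mask(values: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def filter_outliers(
    estimates: Iterable[KrsEstimate],
    alpha: float = 0.05,
    require_all_three: bool = True,
) -> list[KrsEstimate]:
    """Annotate per-cultivar outliers among QC-passing estimates.

    Candidacy: outside 1.5*IQR fences for all three of (krs, krs_area,
    krs_length) — or any one of them if ``require_all_three`` is False.
    Confirmation: membership in the iterative Grubbs flag set on krs.
    Groups with fewer than 3 QC-passing samples fall back to the IQR rule
    alone, with a warning.  Returns new annotated estimates in input order.
    """
    est = list(estimates)
    out = {id(e): False for e in est}
    by_cult: dict[str, list[KrsEstimate]] = {}
    for e in est:
        if e.qc_pass:
            by_cult.setdefault(e.cultivar, []).append(e)
    for cult, group in by_cult.items():
        k = np.array([e.krs for e in group])
        ka = np.array([e.krs_area for e in group])
        kl = np.array([e.krs_length for e in group])
        masks = [_iqr_mask(k), _iqr_mask(ka), _iqr_mask(kl)]
        cand = np.logical_and.reduce(masks) if require_all_three \
            else np.logical_or.reduce(masks)
        if len(group) < 3:
            warnings.warn(
                f"cultivar {cult!r}: fewer than 3 QC-passing samples, "
                "Grubbs test not applicable; IQR-only outlier flags",
                stacklevel=2,
            )
            confirmed = set(np.nonzero(cand)[0])
        else:
            grubbs = grubbs_outlier_indices(k, alpha=alpha)
            confirmed = {i for i in np.nonzero(cand)[0] if i in grubbs}
        for i in confirmed:
            out[id(group[i])] = True
    return [replace(e, outlier=out[id(e)]) for e in est]


def summarize_by_cultivar(estimates: Iterable[KrsEstimate]) -> pd.DataFrame:
    """Mean and SE of unflagged, QC-passing estimates per cultivar.

    Columns: cultivar, release_year, n, and mean/se for krs, krs_area and
    krs_length.  SE is NaN for single-sample groups; empty groups are
    omitted with a warning.
    """
    rows = []
    by_cult: dict[str, list[KrsEstimate]] = {}
    order: list[str] = []
    for e in estimates:
        if e.cultivar not in by_cult:
            by_cult[e.cultivar] = []
            order.append(e.cultivar)
        if e.qc_pass and not e.outlier:
            by_cult[e.cultivar].append(e)
    for cult in order:
        group = by_cult[cult]
        if not group:
            warnings.warn(f"cultivar {cult!r}: no usable estimates, omitted",
                          stacklevel=2)
            continue
        row = {"cultivar": cult, "release_year": group[0].release_year,
               "n": len(group)}
        for name in ("krs", "krs_area", "krs_length"):
            vals = np.array([getattr(e, name) for e in group])
            row[f"{name}_mean"] = vals.mean()
            row[f"{name}_se"] = (vals.std(ddof=1) / math.sqrt(len(vals))
                                 if len(vals) > 1 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
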