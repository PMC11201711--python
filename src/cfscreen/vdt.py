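"""Volume doubling time (VDT) from two serial CT diameter measurements.

A nodule measured at two exams with effective diameters d0 and d1 (mm) a
time interval dt (days) apart, under exponential volume growth with
spherical idealization (V = pi/6 * d^3), has

    VDT = dt * ln 2 / (3 * ln(d1 / d0))     [days]

The effective diameter combines the axial maximum and perpendicular
diameters as their geometric mean sqrt(max * perp); the combination is
isolated in :func:`effective_diameter` so it can be swapped for an
arithmetic-mean convention (the constant cancels in the d1/d0 ratio as long
as both timepoints use the same convention).  Positive VDT means growth,
negative means shrinkage; equal effective diameters leave VDT undefined.
VDT is computed for solid nodules only.  When more than two exams exist,
the first and the last are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .cohort import Density, NoduleObservation

__all__ = [
    "VdtError",
    "VdtEstimate",
    "effective_diameter",
    "volume_from_diameter",
    "vdt",
    "vdt_from_series",
]


class VdtError(ValueError):
    """VDT is undefined or unsupported for the given observations."""


@dataclass(frozen=True)
class VdtEstimate:
    """VDT in days with the effective diameters and interval it came from."""

    vdt_days: float
    d_eff_t0_mm: float
    d_eff_t1_mm: float
    interval_days: float


def effective_diameter(max_mm: float, perp_mm: float) -> float:
    """Geometric mean sqrt(max * perp) of the two measured axes, in mm."""
    if not (perp_mm > 0 and max_mm > 0):
        raise VdtError("diameters must be positive")
    if perp_mm > max_mm + 1e-12:
        raise VdtError(f"perpendicular diameter {perp_mm} exceeds maximum diameter {max_mm}")
    return math.sqrt(max_mm * perp_mm)


def volume_from_diameter(d_mm: float) -> float:
    """Spherical volume pi/6 * d^3 in mm^3."""
    if not d_mm > 0:
        raise VdtError("diameter must be positive")
    return math.pi / 6.0 * d_mm**3


def _observation_d_eff(obs: NoduleObservation) -> float:
    if obs.max_diameter_mm is None or obs.perp_diameter_mm is None:
        raise VdtError(f"nodule {obs.nodule_id}: VDT needs maximum and perpendicular diameters")
    return effective_diameter(obs.max_diameter_mm, obs.perp_diameter_mm)


def vdt(obs0: NoduleObservation, obs1: NoduleObservation) -> VdtEstimate:
    """VDT between two timepoints of the same (solid) nodule.

    Raises VdtError for non-solid density, non-increasing exam days, missing
    axis measurements, or equal effective diameters (undefined growth).
    """
    if obs0.density is not Density.SOLID or obs1.density is not Density.SOLID:
        raise VdtError("VDT is computed for solid nodules only")
    dt = obs1.exam_day - obs0.exam_day
    if dt <= 0:
        raise VdtError("second observation must be later than the first")
    d0 = _observation_d_eff(obs0)
    d1 = _observation_d_eff(obs1)
    if math.isclose(d0, d1, rel_tol=0.0, abs_tol=1e-12):
        raise VdtError("equal effective diameters: doubling time undefined")
    days = dt * math.log(2.0) / (3.0 * math.log(d1 / d0))
    return VdtEstimate(vdt_days=days, d_eff_t0_mm=d0, d_eff_t1_mm=d1, interval_days=float(dt))


def vdt_from_series(observations: Sequence[NoduleObservation]) -> VdtEstimate:
    """VDT from a series of exams of one nodule, using the first and the last."""
    if len(observations) < 2:
        raise VdtError("need at least two observations")
    ordered = sorted(observations, key=lambda o: o.exam_day)
    return vdt(ordered[0], ordered[-1])
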