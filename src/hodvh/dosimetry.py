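"""Dose-coverage indices and the ICRU 83/91 plan-quality indices.

``D_q%`` is the minimum dose received by the hottest q% of the structure
volume, read off the cumulative DVH with linear interpolation in dose.
HI = (D2% − D98%) / D50% quantifies target-dose spread; GI = V50% / V100%
quantifies the steepness of the dose fall-off around the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dvh import DVHCurve, PlanRecord

__all__ = [
    "DosimetricPanel",
    "dose_at_volume",
    "homogeneity_index",
    "gradient_index",
    "compute_dosimetric_panel",
]

_GRID_TOL = 1e-12


def dose_at_volume(curve: DVHCurve, q: float) -> float:
    """Dose (Gy) at which the cumulative volume reaches q percent.

    Linear interpolation in dose on the cumulative curve; on flat segments
    the lowest dose achieving the volume is returned.  If the curve never
    drops to q% (residual hot volume at the end of the grid) the maximum
    grid dose is returned.
    """
    if not 0 < q <= 100:
        raise ValueError(f"q must be in (0, 100], got {q}")
    qf = q / 100.0
    d, c = curve.dose_grid, curve.cum_volume
    below = np.nonzero(c <= qf + _GRID_TOL)[0]
    if below.size == 0:
        return float(d[-1])
    i = int(below[0])
    if i == 0:
        return float(d[0])
    c0, c1 = float(c[i - 1]), float(c[i])
    t = (c0 - qf) / (c0 - c1)
    return float(d[i - 1] + t * (d[i] - d[i - 1]))


def homogeneity_index(d2: float, d98: float, d50: float) -> float:
    """HI = (D2% − D98%) / D50%; zero for a perfectly uniform target dose."""
    if d50 <= 0:
        raise ZeroDivisionError("D50% must be positive to form HI")
    if d2 < d98 - _GRID_TOL:
        raise ValueError(f"D2% ({d2}) must not be below D98% ({d98})")
    return (d2 - d98) / d50


def gradient_index(v50: float, v100: float) -> float:
    """GI = V50% / V100% (isodose volumes in consistent units, e.g. cc)."""
    if v100 <= 0:
        raise ValueError("V100% volume must be positive")
    return v50 / v100


@dataclass(frozen=True)
class DosimetricPanel:
    """The seven dose-distribution indices evaluated per plan."""

    d2: float
    d50: float
    d90: float
    d95: float
    d98: float
    hi: float
    gi: float | None = None

    def __post_init__(self) -> None:
        levels = (self.d2, self.d50, self.d90, self.d95, self.d98)
        if any(np.diff(levels) > _GRID_TOL):
            raise ValueError(f"coverage doses must be non-increasing in q: {levels}")
        if self.d98 < -_GRID_TOL or self.hi < -_GRID_TOL:
            raise ValueError("doses and HI must be non-negative")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "D2": self.d2,
            "D50": self.d50,
            "D90": self.d90,
            "D95": self.d95,
            "D98": self.d98,
            "HI": self.hi,
            "GI": self.gi,
        }


def compute_dosimetric_panel(plan: PlanRecord) -> DosimetricPanel:
    """Evaluate D2/D50/D90/D95/D98, HI and (when isodose volumes are
    recorded) GI for one plan."""
    curve = plan.target_dvh
    d2, d50, d90, d95, d98 = (dose_at_volume(curve, q) for q in (2, 50, 90, 95, 98))
    hi = homogeneity_index(d2, d98, d50)
    gi = None
    if plan.v100_cc is not None and plan.v50_cc is not None:
        gi = gradient_index(plan.v50_cc, plan.v100_cc)
    return DosimetricPanel(d2=d2, d50=d50, d90=d90, d95=d95, d98=d98, hi=hi, gi=gi)
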