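"""Reference cohort summaries for the single-fraction HO prophylaxis study.

Per-arm means and standard deviations of the fourteen evaluated indices for
a 21-patient cohort of single-fraction 7 Gy prophylactic hip irradiation
plans, computed once with inhomogeneity correction disabled (``IC_OFF``,
water-equivalent density) and once recalculated with the correction enabled
(``IC_ON``).  These summaries are the default baseline of the Monte Carlo
resampling study and the calibration targets of the synthetic cohort
generator.  Doses in Gy; HI and GI dimensionless.
"""

from __future__ import annotations

from .dvh import Arm

__all__ = [
    "DOSIMETRIC_INDICES",
    "RADIOBIOLOGICAL_INDICES",
    "ALL_INDICES",
    "COVERAGE_INDICES",
    "REFERENCE_COHORT_N",
    "REFERENCE_COHORT_SUMMARY",
    "reference_baseline",
]

DOSIMETRIC_INDICES = ("D2", "D50", "D90", "D95", "D98", "HI", "GI")
RADIOBIOLOGICAL_INDICES = (
    "gEUD",
    "EUD_LQ_ab3",
    "EUD_LQ_ab10",
    "EQD2_gEUD_ab3",
    "EQD2_gEUD_ab10",
    "EQD2_LQ_ab3",
    "EQD2_LQ_ab10",
)
ALL_INDICES = DOSIMETRIC_INDICES + RADIOBIOLOGICAL_INDICES
#: target-coverage indices whose paired IC-off/IC-on differences drive the study
COVERAGE_INDICES = ("D50", "D90", "D95", "D98")

REFERENCE_COHORT_N = 21

#: index -> arm -> (mean, sd)
REFERENCE_COHORT_SUMMARY: dict[str, dict[Arm, tuple[float, float]]] = {
    "D2": {Arm.IC_OFF: (7.30, 0.22), Arm.IC_ON: (7.31, 0.16)},
    "D50": {Arm.IC_OFF: (7.08, 0.10), Arm.IC_ON: (6.87, 0.19)},
    "D90": {Arm.IC_OFF: (6.80, 0.14), Arm.IC_ON: (6.38, 0.32)},
    "D95": {Arm.IC_OFF: (6.72, 0.18), Arm.IC_ON: (6.20, 0.38)},
    "D98": {Arm.IC_OFF: (6.60, 0.22), Arm.IC_ON: (6.07, 0.39)},
    "HI": {Arm.IC_OFF: (0.10, 0.05), Arm.IC_ON: (0.18, 0.05)},
    "GI": {Arm.IC_OFF: (1.58, 0.60), Arm.IC_ON: (2.84, 1.32)},
    "gEUD": {Arm.IC_OFF: (7.02, 0.09), Arm.IC_ON: (6.80, 0.21)},
    "EUD_LQ_ab3": {Arm.IC_OFF: (7.01, 0.09), Arm.IC_ON: (6.79, 0.21)},
    "EUD_LQ_ab10": {Arm.IC_OFF: (7.00, 0.09), Arm.IC_ON: (6.75, 0.23)},
    "EQD2_gEUD_ab3": {Arm.IC_OFF: (14.07, 0.31), Arm.IC_ON: (13.35, 0.70)},
    "EQD2_gEUD_ab10": {Arm.IC_OFF: (9.96, 0.18), Arm.IC_ON: (9.53, 0.41)},
    "EQD2_LQ_ab3": {Arm.IC_OFF: (14.05, 0.31), Arm.IC_ON: (13.30, 0.71)},
    "EQD2_LQ_ab10": {Arm.IC_OFF: (9.92, 0.19), Arm.IC_ON: (9.44, 0.45)},
}


def reference_baseline(indices: tuple[str, ...] = ALL_INDICES):
    """Return a copy of the reference ``index -> arm -> (mean, sd)`` map."""
    unknown = [i for i in indices if i not in REFERENCE_COHORT_SUMMARY]
    if unknown:
        raise KeyError(f"unknown indices: {unknown}")
    return {i: dict(REFERENCE_COHORT_SUMMARY[i]) for i in indices}
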