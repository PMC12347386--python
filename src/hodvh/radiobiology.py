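"""Equivalent-uniform-dose models and the EQD2 isoeffect conversion.

Two EUD formulations are evaluated on the differential DVH:

* the generalized EUD (Niemierko), the weighted power mean
  ``gEUD = (Σ v_i D_i^a)^(1/a)`` — for ``a = 1`` the arithmetic mean dose;
* the linear–quadratic EUD: the uniform dose producing the same clonogen
  survival as the inhomogeneous distribution under LQ cell kill, i.e. the
  non-negative root ``E`` of

      α·E + (β/n)·E² = −ln Σ_i v_i exp(−α·D_i − β·D_i²/n)

  with ``β = α / (α/β)`` and ``n`` fractions.  A uniform DVH at dose D
  returns exactly D for every admissible (α, β, n).

EQD2 converts a total dose ``D`` delivered at ``d`` Gy per fraction into the
isoeffective total dose in 2 Gy fractions: ``EQD2 = D·(d + α/β)/(2 + α/β)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .dvh import DifferentialDVH, PlanRecord, cumulative_to_differential

__all__ = [
    "RadiobioParams",
    "RadiobioPanel",
    "geud",
    "eud_lq",
    "eqd2",
    "compute_radbio_panel",
]

#: conventional intrinsic radiosensitivity used when only α/β is specified
DEFAULT_ALPHA = 0.3  # Gy^-1


@dataclass(frozen=True)
class RadiobioParams:
    """LQ-model parameter set for one EUD scenario.

    alpha_beta : α/β ratio in Gy (≈3 for late-, ≈10 for early-responding
    tissue); alpha : α in Gy⁻¹; a : gEUD volume-effect exponent
    (a = 1 → mean dose); n_fractions : number of fractions n.
    """

    alpha_beta: float
    alpha: float = DEFAULT_ALPHA
    a: float = 1.0
    n_fractions: int = 1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha_beta <= 0:
            raise ValueError("alpha and alpha_beta must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.a == 0:
            raise ValueError("gEUD exponent a must be non-zero")

    @property
    def beta(self) -> float:
        return self.alpha / self.alpha_beta


def geud(diff: DifferentialDVH, a: float) -> float:
    """Generalized EUD: the a-th power mean of the dose distribution."""
    if a == 0:
        raise ValueError("gEUD exponent a must be non-zero")
    v = diff.partial_volume
    d = diff.bin_dose
    pos = v > 0
    v, d = v[pos], d[pos]
    if np.any(d == 0):
        if a < 0:
            return 0.0  # power-mean limit with a zero-dose cold spot
        keep = d > 0
        v, d = v[keep], d[keep]
        if d.size == 0:
            return 0.0
    log_moment = logsumexp(np.log(v) + a * np.log(d))
    return float(math.exp(log_moment / a))


def eud_lq(diff: DifferentialDVH, params: RadiobioParams) -> float:
    """LQ-model EUD (uniform dose matching the DVH's survival fraction).

    The survival sum is accumulated in the log domain, so the result stays
    finite for arbitrarily large doses as long as some v_i > 0; the root is
    evaluated in the cancellation-free form E = 2L / (α + √(α² + 4βL/n)).
    """
    v = diff.partial_volume
    d = diff.bin_dose
    pos = v > 0
    v, d = v[pos], d[pos]
    n = params.n_fractions
    alpha, beta = params.alpha, params.beta
    log_survival = float(logsumexp(np.log(v) - alpha * d - beta * d**2 / n))
    neg_log_s = max(-log_survival, 0.0)  # ≥ 0; exactly 0 when all doses are 0
    if neg_log_s == 0.0:
        return 0.0
    k = beta / n
    return 2.0 * neg_log_s / (alpha + math.sqrt(alpha * alpha + 4.0 * k * neg_log_s))


def eqd2(total_dose: float, dose_per_fraction: float, alpha_beta: float) -> float:
    """Isoeffective total dose in 2 Gy fractions under the LQ model."""
    if total_dose <= 0 or dose_per_fraction <= 0 or alpha_beta <= 0:
        raise ValueError("total dose, dose per fraction and alpha/beta must be positive")
    return total_dose * (dose_per_fraction + alpha_beta) / (2.0 + alpha_beta)


@dataclass(frozen=True)
class RadiobioPanel:
    """The seven radiobiological indices evaluated per plan (all Gy)."""

    geud: float
    eud_lq_ab3: float
    eud_lq_ab10: float
    eqd2_ab3_geud: float
    eqd2_ab10_geud: float
    eqd2_ab3_lq: float
    eqd2_ab10_lq: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            "gEUD": self.geud,
            "EUD_LQ_ab3": self.eud_lq_ab3,
            "EUD_LQ_ab10": self.eud_lq_ab10,
            "EQD2_gEUD_ab3": self.eqd2_ab3_geud,
            "EQD2_gEUD_ab10": self.eqd2_ab10_geud,
            "EQD2_LQ_ab3": self.eqd2_ab3_lq,
            "EQD2_LQ_ab10": self.eqd2_ab10_lq,
        }


def _eqd2_of_eud(eud: float, n_fractions: int, alpha_beta: float) -> float:
    # dose per fraction of the equivalent uniform course: d = EUD / n
    if eud <= 0:
        return 0.0
    return eqd2(eud, eud / n_fractions, alpha_beta)


def compute_radbio_panel(
    plan: PlanRecord,
    *,
    alpha: float = DEFAULT_ALPHA,
    a: float = 1.0,
) -> RadiobioPanel:
    """Evaluate gEUD, LQ-EUD (α/β = 3 and 10 Gy) and the four EQD2
    conversions for one plan's target DVH."""
    diff = cumulative_to_differential(plan.target_dvh)
    n = plan.n_fractions
    g = geud(diff, a)
    e3 = eud_lq(diff, RadiobioParams(alpha_beta=3.0, alpha=alpha, n_fractions=n))
    e10 = eud_lq(diff, RadiobioParams(alpha_beta=10.0, alpha=alpha, n_fractions=n))
    return RadiobioPanel(
        geud=g,
        eud_lq_ab3=e3,
        eud_lq_ab10=e10,
        eqd2_ab3_geud=_eqd2_of_eud(g, n, 3.0),
        eqd2_ab10_geud=_eqd2_of_eud(g, n, 10.0),
        eqd2_ab3_lq=_eqd2_of_eud(e3, n, 3.0),
        eqd2_ab10_lq=_eqd2_of_eud(e10, n, 10.0),
    )
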