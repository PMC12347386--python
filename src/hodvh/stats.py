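"""Cohort statistics: summaries, normality testing and the exact paired
Wilcoxon signed-rank comparison between IC-off and IC-on plans.

Conventions
-----------
* Summaries report the sample mean, sample SD (denominator n−1) and a
  z-based 95% CI of the mean, mean ± 1.96·SD/√n.
* Normality is assessed with the Shapiro–Wilk test (Royston approximation,
  via scipy); the classical 5% critical-value table for n = 3…50 is embedded
  for reference alongside the p-value decision at α = 0.05.
* The paired comparison is the Wilcoxon signed-rank test with midrank ties,
  zero differences dropped before ranking, and a two-sided p computed from
  the exact null distribution of the signed-rank sum for m ≤ 25 remaining
  pairs (count-distribution recursion over doubled midranks); a normal
  approximation with tie-corrected variance is used above.  The effect size
  is r = |z|/√m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .baseline import ALL_INDICES, DOSIMETRIC_INDICES, RADIOBIOLOGICAL_INDICES
from .dvh import Arm, ManifestError

__all__ = [
    "SummaryStat",
    "NormalityResult",
    "PairedTestResult",
    "CohortSummary",
    "DegenerateDataError",
    "Z_95",
    "summarize",
    "shapiro_wilk",
    "shapiro_wilk_critical_value",
    "sample_skewness",
    "wilcoxon_signed_rank",
    "build_comparison_tables",
]

#: z quantile used for 95% CIs of the mean (normal-approximation convention)
Z_95 = 1.96

ALPHA = 0.05

#: maximum m for which the exact signed-rank null distribution is used
EXACT_WILCOXON_LIMIT = 25


class DegenerateDataError(ValueError):
    """Raised when a test is undefined for the data (e.g. all-zero paired
    differences or a constant sample)."""


@dataclass(frozen=True)
class SummaryStat:
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


def summarize(values: Sequence[float]) -> SummaryStat:
    """Mean, sample SD and z-based 95% CI of the mean."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("summarize requires at least two values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = Z_95 * sd / math.sqrt(x.size)
    return SummaryStat(n=int(x.size), mean=mean, sd=sd, ci_low=mean - half, ci_high=mean + half)


# ---------------------------------------------------------------------------
# normality

# Classical 5% critical values of the Shapiro–Wilk W statistic, n = 3…50.
# A sample is flagged non-normal when W falls below the tabulated value.
_SW_CRITICAL_05 = {
    3: 0.767, 4: 0.748, 5: 0.762, 6: 0.788, 7: 0.803, 8: 0.818, 9: 0.829,
    10: 0.842, 11: 0.850, 12: 0.859, 13: 0.866, 14: 0.874, 15: 0.881,
    16: 0.887, 17: 0.892, 18: 0.897, 19: 0.901, 20: 0.905, 21: 0.908,
    22: 0.911, 23: 0.914, 24: 0.916, 25: 0.918, 26: 0.920, 27: 0.923,
    28: 0.924, 29: 0.926, 30: 0.927, 31: 0.929, 32: 0.930, 33: 0.931,
    34: 0.933, 35: 0.934, 36: 0.935, 37: 0.936, 38: 0.938, 39: 0.939,
    40: 0.940, 41: 0.941, 42: 0.942, 43: 0.943, 44: 0.944, 45: 0.945,
    46: 0.945, 47: 0.946, 48: 0.947, 49: 0.947, 50: 0.947,
}


def shapiro_wilk_critical_value(n: int, alpha: float = ALPHA) -> float:
    """Tabulated Shapiro–Wilk critical W at the given sample size (α = 0.05)."""
    if alpha != ALPHA:
        raise ValueError("critical values are tabulated for alpha = 0.05 only")
    try:
        return _SW_CRITICAL_05[n]
    except KeyError as exc:
        raise ValueError(f"critical W tabulated for 3 <= n <= 50, got n={n}") from exc


@dataclass(frozen=True)
class NormalityResult:
    w_stat: float
    w_critical: float
    skew: float
    effect_size: float
    p_value: float
    reject_h0: bool
    is_normal: bool


def sample_skewness(values: Sequence[float]) -> float:
    """Adjusted Fisher–Pearson standardized third moment."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("skewness requires at least three values")
    if np.ptp(x) == 0:
        raise DegenerateDataError("skewness undefined for a constant sample")
    return float(scipy.stats.skew(x, bias=False))


def shapiro_wilk(values: Sequence[float]) -> NormalityResult:
    """Shapiro–Wilk normality test for small samples (3 ≤ n ≤ 50).

    ``effect_size`` is reported as √(1 − W), the share of ordered-sample
    variation unexplained by the best-fitting normal scores (this package's
    convention; it is descriptive only and plays no role in the decision).
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 50:
        raise ValueError(f"Shapiro–Wilk supported for 3 <= n <= 50, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("Shapiro–Wilk W undefined for a constant sample")
    w, p = scipy.stats.shapiro(x)
    reject = bool(p < ALPHA)
    return NormalityResult(
        w_stat=float(w),
        w_critical=shapiro_wilk_critical_value(int(x.size)),
        skew=sample_skewness(x),
        effect_size=math.sqrt(max(1.0 - float(w), 0.0)),
        p_value=float(p),
        reject_h0=reject,
        is_normal=not reject,
    )


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank


@dataclass(frozen=True)
class PairedTestResult:
    w_signed_rank: float
    p_value: float
    effect_size_r: float
    significant: bool
    n_used: int
    method: str


def _exact_signed_rank_p(w_small: float, ranks: np.ndarray) -> float:
    """Two-sided exact p: 2·P(W+ ≤ w_small) under the symmetric null.

    Midranks are doubled to integers and the null distribution of the
    (doubled) positive-rank sum is built by the count-distribution
    recursion: each rank either joins the positive sum or does not.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    counts = np.zeros(int(r2.sum()) + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r]
    w2 = int(math.floor(2.0 * w_small + 1e-9))
    cdf = counts[: w2 + 1].sum() / 2.0 ** len(r2)
    return min(1.0, 2.0 * cdf)


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact_limit: int = EXACT_WILCOXON_LIMIT,
) -> PairedTestResult:
    """Paired two-sided Wilcoxon signed-rank test of x versus y.

    Zero differences are dropped before ranking; ties among |differences|
    receive midranks.  The reported statistic is the smaller of the
    positive- and negative-rank sums.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    d = x - y
    d = d[d != 0]
    m = int(d.size)
    if m == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w_minus = total - w_plus
    w_small = min(w_plus, w_minus)
    sigma = math.sqrt(float((ranks**2).sum()) / 4.0)  # tie-corrected null SD
    z = (w_plus - total / 2.0) / sigma
    if m <= exact_limit:
        p = _exact_signed_rank_p(w_small, ranks)
        method = "exact"
    else:
        p = float(2.0 * scipy.stats.norm.sf(abs(z)))
        method = "normal"
    return PairedTestResult(
        w_signed_rank=w_small,
        p_value=p,
        effect_size_r=abs(z) / math.sqrt(m),
        significant=bool(p < ALPHA),
        n_used=m,
        method=method,
    )


# ---------------------------------------------------------------------------
# cohort comparison tables


@dataclass(frozen=True)
class CohortSummary:
    """Machine form of the per-index comparison tables (one row per index:
    per-arm summary + normality, and the paired test)."""

    dosimetric: pd.DataFrame
    radiobiological: pd.DataFrame
    n_patients: int

    def combined(self) -> pd.DataFrame:
        return pd.concat([self.dosimetric, self.radiobiological], ignore_index=True)

    def render_text(self) -> str:
        """Plain-text rendering at the study's reporting precision
        (index values 2 dp, p-values 4 dp)."""
        lines: list[str] = []
        for title, frame in (
            ("Dosimetric indices", self.dosimetric),
            ("Radiobiological indices", self.radiobiological),
        ):
            lines.append(title)
            lines.append("-" * len(title))
            header = f"{'Index':<16}{'IC-off mean±SD (95% CI)':<34}{'IC-on mean±SD (95% CI)':<34}{'p':>8}"
            lines.append(header)
            for _, row in frame.iterrows():
                off = _fmt_summary(row, "off")
                on = _fmt_summary(row, "on")
                lines.append(
                    f"{row['index']:<16}{off:<34}{on:<34}{row['p_value']:>8.4f}"
                )
            lines.append("")
        return "\n".join(lines)


def _fmt_summary(row: pd.Series, arm: str) -> str:
    return (
        f"{row[f'mean_{arm}']:.2f} ± {row[f'sd_{arm}']:.2f} "
        f"({row[f'ci_low_{arm}']:.2f}–{row[f'ci_high_{arm}']:.2f})"
    )


def _normality_fields(values: np.ndarray, suffix: str) -> dict[str, float | bool | None]:
    try:
        res = shapiro_wilk(values)
    except (DegenerateDataError, ValueError):
        return {
            f"sw_w_{suffix}": None,
            f"sw_w_critical_{suffix}": None,
            f"skew_{suffix}": None,
            f"sw_effect_size_{suffix}": None,
            f"sw_p_{suffix}": None,
            f"normal_{suffix}": None,
        }
    return {
        f"sw_w_{suffix}": res.w_stat,
        f"sw_w_critical_{suffix}": res.w_critical,
        f"skew_{suffix}": res.skew,
        f"sw_effect_size_{suffix}": res.effect_size,
        f"sw_p_{suffix}": res.p_value,
        f"normal_{suffix}": res.is_normal,
    }


def build_comparison_tables(panels: pd.DataFrame) -> CohortSummary:
    """Build the per-index cohort comparison from a long panel table.

    ``panels`` must have columns ``patient_id``, ``arm`` and one column per
    evaluated index; every patient must appear exactly once per arm.
    """
    required = {"patient_id", "arm"}
    if not required <= set(panels.columns):
        raise ValueError(f"panels frame needs columns {sorted(required)}")
    arm_values = panels["arm"].map(lambda a: a.value if isinstance(a, Arm) else str(a))
    off = panels[arm_values == Arm.IC_OFF.value].set_index("patient_id")
    on = panels[arm_values == Arm.IC_ON.value].set_index("patient_id")
    for frame, name in ((off, "IC_OFF"), (on, "IC_ON")):
        dup = frame.index[frame.index.duplicated()].tolist()
        if dup:
            raise ManifestError(f"duplicate {name} plans for patients: {dup}")
    unpaired = sorted(set(off.index) ^ set(on.index))
    if unpaired:
        raise ManifestError(f"unpaired patients: {unpaired}")
    if len(off) < 2:
        raise ValueError("cohort comparison requires at least two paired patients")
    on = on.loc[off.index]

    indices = [i for i in ALL_INDICES if i in panels.columns]
    rows = []
    for index_name in indices:
        xo = off[index_name].to_numpy(dtype=float)
        xn = on[index_name].to_numpy(dtype=float)
        keep = ~(np.isnan(xo) | np.isnan(xn))
        xo, xn = xo[keep], xn[keep]
        if xo.size < 2:
            continue
        so, sn = summarize(xo), summarize(xn)
        row: dict = {"index": index_name, "n": int(xo.size)}
        for stat, suffix in ((so, "off"), (sn, "on")):
            row.update(
                {
                    f"mean_{suffix}": stat.mean,
                    f"sd_{suffix}": stat.sd,
                    f"ci_low_{suffix}": stat.ci_low,
                    f"ci_high_{suffix}": stat.ci_high,
                }
            )
        row.update(_normality_fields(xo, "off"))
        row.update(_normality_fields(xn, "on"))
        try:
            test = wilcoxon_signed_rank(xo, xn)
            row.update(
                {
                    "wilcoxon_w": test.w_signed_rank,
                    "p_value": test.p_value,
                    "effect_size_r": test.effect_size_r,
                    "significant": test.significant,
                    "test_method": test.method,
                }
            )
        except DegenerateDataError:
            row.update(
                {
                    "wilcoxon_w": None,
                    "p_value": float("nan"),
                    "effect_size_r": None,
                    "significant": False,
                    "test_method": "degenerate",
                }
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    dosi = frame[frame["index"].isin(DOSIMETRIC_INDICES)].reset_index(drop=True)
    radbio = frame[frame["index"].isin(RADIOBIOLOGICAL_INDICES)].reset_index(drop=True)
    return CohortSummary(dosimetric=dosi, radiobiological=radbio, n_patients=len(off))
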