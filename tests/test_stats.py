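import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from hodvh.baseline import ALL_INDICES
from hodvh.dvh import ManifestError
from hodvh.stats import (
    DegenerateDataError,
    build_comparison_tables,
    sample_skewness,
    shapiro_wilk,
    shapiro_wilk_critical_value,
    summarize,
    wilcoxon_signed_rank,
)


def standardized_normal_grid(n: int) -> np.ndarray:
    """Exact normal quantile grid rescaled to mean 0, sample SD 1."""
    z = scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return (z - z.mean()) / z.std(ddof=1)


class TestSummarize:
    def test_reference_ci_d50(self):
        x = 7.08 + 0.10 * standardized_normal_grid(21)
        s = summarize(x)
        assert round(s.ci_low, 2) == 7.04 and round(s.ci_high, 2) == 7.12

    def test_reference_ci_mean_dose(self):
        x = 7.02 + 0.09 * standardized_normal_grid(21)
        s = summarize(x)
        assert round(s.ci_low, 2) == 6.98 and round(s.ci_high, 2) == 7.06

    def test_constant_sample(self):
        s = summarize([5.0, 5.0, 5.0])
        assert s.sd == 0.0 and s.ci_low == s.ci_high == 5.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        a, b = summarize(x), summarize(rng.permutation(x))
        assert a.mean == pytest.approx(b.mean, abs=1e-12)
        assert a.sd == pytest.approx(b.sd, abs=1e-12)
        assert a.ci_low == pytest.approx(b.ci_low, abs=1e-12)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            summarize([1.0])


class TestShapiroWilk:
    def test_reference_critical_value_n21(self):
        assert shapiro_wilk_critical_value(21) == 0.908

    def test_critical_value_range(self):
        with pytest.raises(ValueError):
            shapiro_wilk_critical_value(2)
        with pytest.raises(ValueError):
            shapiro_wilk_critical_value(51)

    def test_normal_grid_passes(self):
        res = shapiro_wilk(standardized_normal_grid(21))
        assert res.w_stat > 0.95 and res.p_value > 0.05
        assert res.is_normal and not res.reject_h0
        assert res.w_critical == 0.908

    def test_right_skewed_sample_rejected(self):
        res = shapiro_wilk(np.exp(2 * standardized_normal_grid(21)))
        assert res.reject_h0 and not res.is_normal
        assert res.skew > 1.0

    def test_scale_and_location_invariance(self):
        x = np.random.default_rng(5).normal(size=20)
        base = shapiro_wilk(x).w_stat
        assert shapiro_wilk(3.5 * x - 7.0).w_stat == pytest.approx(base, abs=1e-8)
        assert shapiro_wilk(-2.0 * x + 1.0).w_stat == pytest.approx(base, abs=1e-8)

    def test_constant_sample_undefined(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([1.0] * 10)

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestSkewness:
    def test_symmetric_sample_zero(self):
        assert sample_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # adjusted Fisher-Pearson for (0, 0, 1): g1 = m3/m2^1.5, G1 = g1*sqrt(n(n-1))/(n-2)
        x = np.array([0.0, 0.0, 1.0])
        m2 = ((x - x.mean()) ** 2).mean()
        m3 = ((x - x.mean()) ** 3).mean()
        expected = (m3 / m2**1.5) * math.sqrt(3 * 2) / 1
        assert sample_skewness(x) == pytest.approx(expected, abs=1e-12)
        assert sample_skewness(x) > 0

    def test_antisymmetry(self):
        x = np.random.default_rng(2).exponential(size=25)
        assert sample_skewness(-x) == pytest.approx(-sample_skewness(x), abs=1e-12)


def enumeration_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by brute enumeration of all 2^m sign assignments."""
    d = (x - y).astype(float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count_le = sum(
        1
        for signs in itertools.product((0, 1), repeat=len(d))
        if np.compress(signs, ranks).sum() <= w_obs + 1e-9
    )
    return w_obs, min(1.0, 2.0 * count_le / 2 ** len(d))


class TestWilcoxon:
    def test_three_positive_pairs(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.5, 1.0, 1.5])
        assert res.w_signed_rank == 0.0
        assert res.p_value == pytest.approx(0.25, abs=1e-12)
        assert res.method == "exact"

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("m", [4, 6, 8, 10, 12])
    def test_exact_p_matches_enumeration(self, m):
        rng = np.random.default_rng(m)
        for _ in range(10):
            # mixture of continuous and tied/zero differences
            x = np.round(rng.normal(0.3, 1.0, size=m), 1)
            y = np.zeros(m)
            if np.all(x == 0):
                continue
            w_oracle, p_oracle = enumeration_oracle(x, y)
            res = wilcoxon_signed_rank(x, y)
            assert res.w_signed_rank == pytest.approx(w_oracle, abs=1e-9)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            d = rng.normal(0.5, 1.0, size=12)
            ref = scipy.stats.wilcoxon(d, mode="exact")
            res = wilcoxon_signed_rank(d, np.zeros_like(d))
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_above_exact_limit(self):
        rng = np.random.default_rng(23)
        d = rng.normal(0.8, 1.0, size=40)
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert res.method == "normal"
        assert 0 < res.p_value < 0.05
        assert 0 < res.effect_size_r <= 1.0

    def test_uniform_shift_with_noise_significant_at_n21(self):
        rng = np.random.default_rng(9)
        off = rng.normal(7.0, 0.1, size=21)
        on = off - 0.2 + rng.normal(0, 0.05, size=21)
        assert wilcoxon_signed_rank(off, on).significant


class TestComparisonTables:
    @staticmethod
    def _panels(n=12, shift=0.2, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            base = {name: rng.normal(7.0, 0.1) for name in ALL_INDICES}
            rows.append({"patient_id": f"P{i}", "arm": "IC_OFF", **base})
            rows.append(
                {
                    "patient_id": f"P{i}",
                    "arm": "IC_ON",
                    **{k: v - shift + rng.normal(0, 0.02) for k, v in base.items()},
                }
            )
        return pd.DataFrame(rows)

    def test_emits_all_fourteen_rows(self):
        summary = build_comparison_tables(self._panels())
        assert len(summary.dosimetric) == 7
        assert len(summary.radiobiological) == 7
        assert summary.n_patients == 12
        assert summary.combined()["significant"].all()

    def test_unpaired_patient_reported(self):
        panels = self._panels().iloc[:-1]  # drop one IC_ON plan
        with pytest.raises(ManifestError, match="P11"):
            build_comparison_tables(panels)

    def test_identical_arms_degenerate_not_significant(self):
        panels = self._panels(shift=0.0)
        panels_on = panels[panels.arm == "IC_ON"].copy()
        off_vals = panels[panels.arm == "IC_OFF"].set_index("patient_id")
        for col in ALL_INDICES:
            panels_on[col] = off_vals.loc[panels_on.patient_id, col].to_numpy()
        merged = pd.concat([panels[panels.arm == "IC_OFF"], panels_on])
        summary = build_comparison_tables(merged)
        assert not summary.combined()["significant"].any()
        assert (summary.combined()["test_method"] == "degenerate").all()

    def test_render_text_has_expected_shape(self):
        text = build_comparison_tables(self._panels()).render_text()
        assert "Dosimetric indices" in text and "Radiobiological indices" in text
        assert "gEUD" in text and "HI" in text
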