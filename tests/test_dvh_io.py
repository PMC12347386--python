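import numpy as np
import pytest
from hypothesis import given, strategies as st

from hodvh.dvh import (
    Arm,
    DVHCurve,
    DVHFormatError,
    DVHValidationError,
    DifferentialDVH,
    ManifestError,
    PlanRecord,
    cumulative_to_differential,
    differential_to_cumulative,
    load_cohort,
    read_dvh_file,
    save_cohort,
    write_dvh_file,
)

from conftest import random_cumulative


class TestReading:
    def test_percent_volumes_rescaled_to_fractions(self, tmp_path):
        p = tmp_path / "a.dvh"
        p.write_text("# structure: CTV\ndose_gy,volume_pct\n0,100\n7,50\n8,0\n")
        (curve,) = read_dvh_file(p)
        assert curve.structure_label == "CTV"
        np.testing.assert_allclose(curve.cum_volume, [1.0, 0.5, 0.0])

    def test_single_row_degenerate_curve(self, tmp_path):
        p = tmp_path / "a.dvh"
        p.write_text("dose,volume\n0,100\n")
        (curve,) = read_dvh_file(p)
        assert curve.dose_grid.tolist() == [0.0]
        assert curve.cum_volume.tolist() == [1.0]

    def test_non_monotone_dose_error_names_row(self, tmp_path):
        p = tmp_path / "a.dvh"
        p.write_text("dose,volume\n0,100\n5,60\n4,70\n")
        with pytest.raises(DVHFormatError, match="row 4"):
            read_dvh_file(p)

    def test_increasing_volume_error_names_row(self, tmp_path):
        p = tmp_path / "a.dvh"
        p.write_text("dose,volume\n0,100\n5,60\n6,70\n")
        with pytest.raises(DVHValidationError, match="row 4"):
            read_dvh_file(p)

    def test_curve_not_starting_at_zero_is_extended(self, tmp_path):
        p = tmp_path / "a.dvh"
        p.write_text("dose,volume\n5,100\n7,0\n")
        (curve,) = read_dvh_file(p)
        assert curve.dose_grid[0] == 0.0 and curve.cum_volume[0] == 1.0

    def test_absolute_cc_volumes(self, tmp_path):
        p = tmp_path / "a.dvh"
        p.write_text("dose,volume_cc\n0,200\n7,100\n8,0\n")
        (curve,) = read_dvh_file(p, volume_unit="cc")
        assert curve.total_volume_cc == 200.0
        np.testing.assert_allclose(curve.cum_volume, [1.0, 0.5, 0.0])

    def test_multiple_curves_per_file(self, tmp_path):
        p = tmp_path / "a.dvh"
        p.write_text("# A\n0,100\n7,0\n# B\n0,100\n6,50\n7,0\n")
        curves = read_dvh_file(p)
        assert [c.structure_label for c in curves] == ["A", "B"]


class TestWriterRoundTrip:
    def test_written_file_reproduces_curve_bitwise(self, tmp_path, two_step_curve):
        path = write_dvh_file(two_step_curve, tmp_path / "c.dvh")
        (back,) = read_dvh_file(path)
        assert back.dose_grid.tolist() == two_step_curve.dose_grid.tolist()
        assert back.cum_volume.tolist() == two_step_curve.cum_volume.tolist()

    @given(st.integers(0, 10_000))
    def test_random_curves_round_trip_bitwise(self, tmp_path_factory, seed):
        curve = random_cumulative(np.random.default_rng(seed))
        path = tmp_path_factory.mktemp("dvh") / "c.dvh"
        write_dvh_file(curve, path)
        (back,) = read_dvh_file(path)
        assert back.dose_grid.tolist() == curve.dose_grid.tolist()
        assert back.cum_volume.tolist() == curve.cum_volume.tolist()


class TestConversion:
    def test_two_step_bins_are_hand_differences(self, two_step_curve):
        diff = cumulative_to_differential(two_step_curve)
        np.testing.assert_allclose(diff.bin_dose, [3.5, 7.5])
        np.testing.assert_allclose(diff.partial_volume, [0.5, 0.5])

    def test_uniform_box_concentrates_near_prescription(self, box_curve):
        diff = cumulative_to_differential(box_curve)
        # one effective bin of weight ~1 near 7 Gy
        near = np.abs(diff.bin_dose - 7.0) < 0.01
        assert diff.partial_volume[near].sum() == pytest.approx(1.0, abs=1e-9)

    def test_residual_hot_volume_absorbed_at_last_dose(self):
        curve = DVHCurve("t", [0.0, 6.0, 7.0], [1.0, 0.8, 0.3])
        diff = cumulative_to_differential(curve)
        assert diff.bin_dose[-1] == 7.0
        assert diff.partial_volume[-1] == pytest.approx(0.3, abs=1e-12)
        assert diff.partial_volume.sum() == pytest.approx(1.0, abs=1e-9)

    def test_differential_to_cumulative_tail_sums(self):
        diff = DifferentialDVH([3.5, 7.5], [0.5, 0.5])
        curve = differential_to_cumulative(diff)
        assert curve.dose_grid.tolist() == [0.0, 3.5, 7.5]
        np.testing.assert_allclose(curve.cum_volume, [1.0, 0.5, 0.0])

    def test_single_bin_step_curve(self):
        curve = differential_to_cumulative(DifferentialDVH([7.0], [1.0]))
        assert curve.dose_grid.tolist() == [0.0, 7.0]
        np.testing.assert_allclose(curve.cum_volume, [1.0, 0.0])

    @given(st.integers(0, 10_000))
    def test_round_trips_conserve_volume(self, seed):
        rng = np.random.default_rng(seed)
        curve = random_cumulative(rng)
        diff = cumulative_to_differential(curve)
        assert diff.partial_volume.sum() == pytest.approx(1.0, abs=1e-9)
        back = cumulative_to_differential(differential_to_cumulative(diff))
        assert back.partial_volume.sum() == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 10_000))
    def test_diff_cum_diff_conserves_each_bin_volume(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 10))
        doses = np.sort(rng.uniform(0.5, 10.0, size=k))
        doses += np.arange(k) * 1e-3  # ensure distinct doses
        v = rng.uniform(0.05, 1.0, size=k)
        diff = DifferentialDVH(doses, v / v.sum())
        back = cumulative_to_differential(differential_to_cumulative(diff))
        np.testing.assert_allclose(back.partial_volume, diff.partial_volume, atol=1e-9)


class TestInvariants:
    def test_curve_must_start_at_zero(self):
        with pytest.raises(DVHValidationError):
            DVHCurve("t", [1.0, 2.0], [1.0, 0.0])

    def test_curve_must_be_non_increasing(self):
        with pytest.raises(DVHValidationError):
            DVHCurve("t", [0.0, 1.0, 2.0], [1.0, 0.5, 0.6])

    def test_differential_volumes_must_sum_to_one(self):
        with pytest.raises(DVHValidationError):
            DifferentialDVH([1.0, 2.0], [0.5, 0.4])

    def test_plan_requires_consistent_isodose_volumes(self, two_step_curve):
        with pytest.raises(DVHValidationError):
            PlanRecord("P1", Arm.IC_OFF, two_step_curve, v100_cc=100.0, v50_cc=50.0)


class TestManifest:
    def _plans(self, curve):
        return [
            PlanRecord("P001", Arm.IC_OFF, curve, v100_cc=100.0, v50_cc=160.0),
            PlanRecord("P001", Arm.IC_ON, curve, v100_cc=90.0, v50_cc=250.0),
        ]

    def test_save_load_round_trip(self, tmp_path, two_step_curve):
        manifest = save_cohort(self._plans(two_step_curve), tmp_path)
        plans = load_cohort(manifest)
        assert [(p.patient_id, p.arm) for p in plans] == [
            ("P001", Arm.IC_OFF),
            ("P001", Arm.IC_ON),
        ]
        assert plans[0].v50_cc == 160.0
        np.testing.assert_array_equal(plans[1].target_dvh.cum_volume, two_step_curve.cum_volume)

    def test_missing_dvh_file_reported(self, tmp_path, two_step_curve):
        manifest = save_cohort(self._plans(two_step_curve), tmp_path)
        (tmp_path / "P001_IC_ON.dvh").unlink()
        with pytest.raises(ManifestError, match="IC_ON"):
            load_cohort(manifest)

    def test_unknown_arm_rejected(self, tmp_path, two_step_curve):
        manifest = save_cohort(self._plans(two_step_curve), tmp_path)
        text = manifest.read_text().replace("IC_ON", "IC_MAYBE")
        manifest.write_text(text)
        with pytest.raises(ManifestError, match="arm"):
            load_cohort(manifest)
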