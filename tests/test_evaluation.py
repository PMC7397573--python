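import numpy as np
import pytest

from kbplan.evaluation import (
    Criterion,
    DoseGrid,
    check_criteria,
    compute_dvh,
    conformity_index,
    criteria_from_yaml,
    criteria_to_yaml,
    default_criteria,
    dose_at_cc,
    dose_at_volume,
    homogeneity_index,
    max_dose,
    results_to_json,
    volume_at_dose,
)
from kbplan.volumes import StructureError, StructureSet, VoxelGrid

from _oracles import (
    oracle_ci,
    oracle_dose_at_cc,
    oracle_dose_at_volume,
    oracle_volume_at_dose,
    random_blob,
)
from conftest import make_mask


def uniform_dose(grid, value):
    return DoseGrid(grid, np.full(grid.shape, float(value)))


@pytest.fixture
def box_mask(small_grid):
    v = np.zeros(small_grid.shape, bool)
    v[4:12, 4:12, 4:10] = True
    return make_mask(small_grid, v, "box")


class TestDoseAtVolume:
    def test_uniform_dose_returns_itself(self, small_grid, box_mask):
        assert dose_at_volume(uniform_dose(small_grid, 60.0), box_mask, 95) == 60.0

    def test_four_voxel_interpolation_rule(self):
        grid = VoxelGrid((4, 1, 1), (1.0, 1.0, 1.0))
        m = make_mask(grid, np.ones(grid.shape, bool))
        dose = DoseGrid(grid, np.array([10.0, 20.0, 30.0, 40.0]).reshape(4, 1, 1))
        # descending (40,30,20,10); f = 0.5*4 = 2 -> index 1 -> 30
        assert dose_at_volume(dose, m, 50) == 30.0
        assert dose_at_volume(dose, m, 50) == oracle_dose_at_volume(
            np.array([10.0, 20.0, 30.0, 40.0]), 50)

    def test_ordering_property(self, small_grid, box_mask, rng):
        dose = DoseGrid(small_grid, rng.random(small_grid.shape) * 70)
        d100 = dose_at_volume(dose, box_mask, 100)
        d95 = dose_at_volume(dose, box_mask, 95)
        d5 = dose_at_volume(dose, box_mask, 5)
        assert d100 <= d95 <= d5 <= max_dose(dose, box_mask)

    def test_invalid_percent_rejected(self, small_grid, box_mask):
        with pytest.raises(ValueError):
            dose_at_volume(uniform_dose(small_grid, 1.0), box_mask, 0)

    def test_empty_mask_rejected(self, small_grid):
        empty = make_mask(small_grid, np.zeros(small_grid.shape, bool))
        with pytest.raises(StructureError, match="empty"):
            dose_at_volume(uniform_dose(small_grid, 1.0), empty, 95)


class TestVolumeAtDose:
    def test_uniform_dose_fully_covered(self, small_grid, box_mask):
        assert volume_at_dose(uniform_dose(small_grid, 60.0), box_mask, 30) == 100.0

    def test_threshold_above_max_gives_zero(self, small_grid, box_mask, rng):
        dose = DoseGrid(small_grid, rng.random(small_grid.shape) * 10)
        assert volume_at_dose(dose, box_mask, 11.0) == 0.0

    def test_matches_voxel_count_oracle(self, small_grid, box_mask, rng):
        dose = DoseGrid(small_grid, rng.random(small_grid.shape) * 70)
        got = volume_at_dose(dose, box_mask, 35.0)
        assert got == oracle_volume_at_dose(dose.dose_Gy[box_mask.voxels], 35.0)


class TestDoseAtCc:
    def test_uniform_dose_for_any_cc(self, small_grid, box_mask):
        assert dose_at_cc(uniform_dose(small_grid, 42.0), box_mask, 1.0) == 42.0

    def test_matches_sort_oracle(self, small_grid, box_mask, rng):
        dose = DoseGrid(small_grid, rng.random(small_grid.shape) * 70)
        inside = dose.dose_Gy[box_mask.voxels]
        got = dose_at_cc(dose, box_mask, 1.0)
        assert got == oracle_dose_at_cc(inside, 1.0, small_grid.voxel_volume_cc)

    def test_monotone_in_volume(self, small_grid, box_mask, rng):
        dose = DoseGrid(small_grid, rng.random(small_grid.shape) * 70)
        assert dose_at_cc(dose, box_mask, 1.0) >= dose_at_cc(dose, box_mask, 2.0)

    def test_cc_beyond_structure_volume_rejected(self, small_grid, box_mask):
        with pytest.raises(ValueError, match="exceeds"):
            dose_at_cc(uniform_dose(small_grid, 1.0), box_mask, 1e6)


class TestConformityAndHomogeneity:
    def test_exact_coverage_gives_ci_one(self, small_grid, box_mask):
        dose = np.zeros(small_grid.shape)
        dose[box_mask.voxels] = 60.0
        assert conformity_index(DoseGrid(small_grid, dose), box_mask, 60.0) == 1.0

    def test_equal_external_spill_halves_ci(self, small_grid):
        v = np.zeros(small_grid.shape, bool)
        v[2:6, 2:6, 2:6] = True
        m = make_mask(small_grid, v, "ptv")
        dose = np.zeros(small_grid.shape)
        dose[2:6, 2:6, 2:6] = 60.0
        dose[10:14, 10:14, 10:14] = 60.0  # equal volume outside the PTV
        assert conformity_index(DoseGrid(small_grid, dose), m, 60.0) == pytest.approx(0.5)

    def test_ci_matches_voxel_count_oracle(self, small_grid, box_mask, rng):
        dose = rng.random(small_grid.shape) * 70
        got = conformity_index(DoseGrid(small_grid, dose), box_mask, 50.0)
        assert got == pytest.approx(oracle_ci(dose, box_mask.voxels, 50.0))
        assert 0.0 <= got <= 1.0

    def test_no_coverage_gives_zero_ci(self, small_grid, box_mask):
        assert conformity_index(uniform_dose(small_grid, 10.0), box_mask, 60.0) == 0.0

    def test_uniform_dose_has_hi_one(self, small_grid, box_mask):
        assert homogeneity_index(uniform_dose(small_grid, 60.0), box_mask) == 1.0

    def test_hi_is_scale_invariant(self, small_grid, box_mask, rng):
        dose = rng.random(small_grid.shape) * 60 + 5
        hi1 = homogeneity_index(DoseGrid(small_grid, dose), box_mask)
        hi2 = homogeneity_index(DoseGrid(small_grid, dose * 3), box_mask)
        assert hi1 == pytest.approx(hi2)
        assert hi1 >= 1.0

    def test_zero_d95_is_undefined(self, small_grid, box_mask):
        with pytest.raises(ValueError, match="undefined HI"):
            homogeneity_index(uniform_dose(small_grid, 0.0), box_mask)


class TestDVHCurve:
    def test_starts_at_one_and_non_increasing(self, small_grid, box_mask, rng):
        dose = DoseGrid(small_grid, rng.random(small_grid.shape) * 70)
        curve = compute_dvh(dose, box_mask)
        assert curve.cumulative_volume_fraction[0] == 1.0
        assert np.all(np.diff(curve.cumulative_volume_fraction) <= 0)

    def test_inverse_consistency_with_dose_at_volume(self, small_grid, box_mask, rng):
        # consistent up to the interpolation convention: the count at the
        # interpolated dose can fall short of x by at most one voxel
        dose = DoseGrid(small_grid, rng.random(small_grid.shape) * 70)
        one_voxel_percent = 100.0 / box_mask.voxel_count
        for x in (20.0, 50.0, 90.0):
            dx = dose_at_volume(dose, box_mask, x)
            assert volume_at_dose(dose, box_mask, dx) >= x - one_voxel_percent - 1e-9


class TestCriteria:
    def _set_with(self, grid, **masks):
        s = StructureSet("t", grid)
        for name, v in masks.items():
            s.add(make_mask(grid, v, name.replace("_", " ") if " " in name else name))
        return s

    def test_primary_target_criterion_passes_at_70(self, small_grid):
        v = np.zeros(small_grid.shape, bool)
        v[4:12, 4:12, 4:10] = True
        s = StructureSet("t", small_grid)
        s.add(make_mask(small_grid, v, "GTV_T_P"))
        results = check_criteria(uniform_dose(small_grid, 70.0), s,
                                 [Criterion("GTV_T_P", "D%", 95, 68.96, 70.96)])
        assert results[0].passed and results[0].value == 70.0

    def test_lens_overdose_fails(self, small_grid):
        v = np.zeros(small_grid.shape, bool)
        v[1:3, 1:3, 1:3] = True
        s = StructureSet("t", small_grid)
        s.add(make_mask(small_grid, v, "left optic lens"))
        results = check_criteria(uniform_dose(small_grid, 9.0), s,
                                 [Criterion("left optic lens", "Dmax", None, None, 8.0)])
        assert not results[0].passed

    def test_boundary_equality_fails_strict_comparator(self, small_grid):
        v = np.zeros(small_grid.shape, bool)
        v[1:5, 1:5, 1:5] = True
        s = StructureSet("t", small_grid)
        s.add(make_mask(small_grid, v, "spinal cord"))
        results = check_criteria(uniform_dose(small_grid, 45.0), s,
                                 [Criterion("spinal cord", "D%", 1, None, 45.0)])
        assert not results[0].passed

    def test_missing_structure_is_named(self, small_grid):
        s = StructureSet("t", small_grid)
        with pytest.raises(StructureError, match="brainstem"):
            check_criteria(uniform_dose(small_grid, 1.0), s,
                           [Criterion("brainstem", "Dcc", 1, None, 65.0)])

    def test_default_criteria_cover_protocol(self):
        crits = default_criteria()
        rois = [c.roi for c in crits]
        assert len(crits) == 17
        assert "GTV_T_P" in rois and "optic chiasm" in rois
        cord = next(c for c in crits if c.roi == "spinal cord")
        assert cord.metric == "D%" and cord.arg == 1  # D1 is percent-volume

    def test_yaml_round_trip(self):
        crits = default_criteria()
        assert criteria_from_yaml(criteria_to_yaml(crits)) == crits

    def test_json_report_is_well_formed(self, small_grid, rng):
        import json

        v = random_blob(rng, small_grid.shape, small_grid.spacing_mm)
        s = StructureSet("t", small_grid)
        s.add(make_mask(small_grid, v, "brainstem"))
        results = check_criteria(DoseGrid(small_grid, rng.random(small_grid.shape) * 70),
                                 s, [Criterion("brainstem", "Dcc", 1, None, 65.0)])
        parsed = json.loads(results_to_json(results))
        assert parsed[0]["roi"] == "brainstem"
        assert isinstance(parsed[0]["passed"], bool)
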