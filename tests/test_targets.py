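import itertools

import numpy as np
import pytest

from sirtboost import (
    DoseGrid,
    Lesion,
    SelectionConfig,
    StructureMask,
    build_boost_targets,
    classify_lesions,
    debulking_stats,
    expand_to_ptv,
    extract_boost_subvolume,
    lesion_from_mask,
    volume_cc,
)

from conftest import make_mask


def _lesion(lid, mean_dose, volume_cc=10.0, mask=None):
    mask = mask if mask is not None else make_mask(np.ones((3, 3, 3), bool), name=lid)
    return Lesion(id=lid, gtv=mask, mean_dose_corrected=mean_dose,
                  d90_uncorrected=mean_dose * 0.5, volume_cc=volume_cc)


class TestClassifyLesions:
    def test_boundary_dose_excluded(self):
        # a lesion at exactly the threshold counts as a predicted responder
        excluded, eligible = classify_lesions([_lesion("a", 292.0)])
        assert [l.id for l in excluded] == ["a"] and not eligible

    def test_low_dose_eligible(self):
        excluded, eligible = classify_lesions([_lesion("a", 5.0)])
        assert not excluded and [l.id for l in eligible] == ["a"]

    def test_all_high_dose_gives_empty_eligible_set(self):
        lesions = [_lesion(f"l{i}", 1709.0) for i in range(3)]
        excluded, eligible = classify_lesions(lesions)
        assert len(excluded) == 3 and eligible == []

    def test_order_preserved_and_partition_complete(self):
        doses = [100, 400, 50, 292, 291.999]
        lesions = [_lesion(f"l{i}", d) for i, d in enumerate(doses)]
        excluded, eligible = classify_lesions(lesions)
        assert [l.id for l in excluded] == ["l1", "l3"]
        assert [l.id for l in eligible] == ["l0", "l2", "l4"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            classify_lesions([])


class TestBoostSubvolume:
    def _case(self, doses):
        doses = np.asarray(doses, float).reshape(-1, 1, 1)
        dose = DoseGrid(doses, (1, 1, 1))
        gtv = StructureMask(np.ones_like(doses, bool), (1, 1, 1), name="gtv_1")
        return dose, gtv

    def test_fully_covered_gtv_gives_empty_subvolume(self):
        dose, gtv = self._case([70.0, 100.0, 500.0])
        sub = extract_boost_subvolume(gtv, dose)
        assert sub.is_empty()

    def test_fully_underdosed_gtv_kept_whole(self):
        dose, gtv = self._case([5.0, 30.0, 69.9])
        sub = extract_boost_subvolume(gtv, dose)
        assert sub.voxel_count == gtv.voxel_count

    def test_mixed_gtv_keeps_exactly_cold_voxels(self, rng):
        doses = rng.uniform(0, 140, 100)
        dose, gtv = self._case(doses)
        sub = extract_boost_subvolume(gtv, dose)
        np.testing.assert_array_equal(sub.values.ravel(), doses < 70.0)

    def test_monotone_in_threshold(self, rng):
        doses = rng.uniform(0, 140, 100)
        dose, gtv = self._case(doses)
        lo = extract_boost_subvolume(gtv, dose, SelectionConfig(voxel_threshold_gy=50))
        hi = extract_boost_subvolume(gtv, dose, SelectionConfig(voxel_threshold_gy=90))
        assert np.all(hi.values[lo.values])


def brute_force_ptv(target, margins_mm):
    """Independent O(N^2-ish) neighbourhood scan of the ellipsoid rule."""
    ml, mr, ma, mp, ms, mi = margins_mm
    sx, sy, sz = target.spacing
    out = np.zeros_like(target.values)
    coords = np.argwhere(target.values)
    for i, j, k in itertools.product(*map(range, target.values.shape)):
        for ti, tj, tk in coords:
            dx, dy, dz = (i - ti) * sx, (j - tj) * sy, (k - tk) * sz
            q = 0.0
            ok = True
            for delta, neg, pos in ((dx, ml, mr), (dy, mp, ma), (dz, mi, ms)):
                if delta == 0:
                    continue
                m = pos if delta > 0 else neg
                if m == 0:
                    ok = False
                    break
                q += (delta / m) ** 2
            if ok and q <= 1.0 + 1e-12:
                out[i, j, k] = True
                break
    return out


class TestPTVExpansion:
    def test_zero_margins_identity(self, rng):
        target = make_mask(rng.random((6, 6, 6)) < 0.3)
        ptv = expand_to_ptv(target, (0, 0, 0, 0, 0, 0))
        np.testing.assert_array_equal(ptv.values, target.values)

    def test_single_voxel_matches_exhaustive_scan(self):
        vals = np.zeros((11, 11, 13), bool)
        vals[5, 5, 6] = True
        target = make_mask(vals, spacing=(2, 2, 2))
        ptv = expand_to_ptv(target, (5, 5, 5, 5, 8, 8))
        np.testing.assert_array_equal(ptv.values,
                                      brute_force_ptv(target, (5, 5, 5, 5, 8, 8)))

    @pytest.mark.parametrize("margins", [
        (5, 5, 5, 5, 8, 8),
        (3, 6, 2, 4, 0, 7),   # asymmetric, one zero direction
    ])
    def test_random_target_matches_exhaustive_scan(self, margins, rng):
        vals = rng.random((9, 9, 9)) < 0.08
        vals[4, 4, 4] = True
        target = make_mask(vals, spacing=(1.7, 2.0, 2.5))
        ptv = expand_to_ptv(target, margins)
        np.testing.assert_array_equal(ptv.values, brute_force_ptv(target, margins))

    def test_larger_si_margin_nests(self):
        vals = np.zeros((15, 15, 15), bool)
        vals[7, 7, 7] = True
        target = make_mask(vals, spacing=(2, 2, 2))
        small = expand_to_ptv(target, (5, 5, 5, 5, 5, 5))
        large = expand_to_ptv(target, (5, 5, 5, 5, 8, 8))
        assert np.all(large.values[small.values])
        assert large.voxel_count > small.voxel_count

    def test_clipped_at_grid_boundary(self):
        vals = np.zeros((3, 3, 3), bool)
        vals[0, 0, 0] = True
        ptv = expand_to_ptv(make_mask(vals, spacing=(1, 1, 1)), (5, 5, 5, 5, 8, 8))
        assert ptv.values.shape == vals.shape  # expansion silently clipped


class TestBuildBoostTargets:
    def _dose_and_lesions(self, lesion_doses, spacing=(4, 4, 4)):
        # 4 mm voxels make each 64-voxel lesion 4.1 cc, above the 2 cc
        # evaluability floor
        shape = (20, 12, 12)
        dose_vals = np.zeros(shape)
        lesions = []
        for idx, (lid, dose_gy) in enumerate(lesion_doses):
            vals = np.zeros(shape, bool)
            vals[idx * 6:idx * 6 + 4, 4:8, 4:8] = True
            dose_vals[vals] = dose_gy
            mask = StructureMask(vals, spacing, name=lid)
            lesions.append(Lesion(lid, mask, mean_dose_corrected=dose_gy,
                                  d90_uncorrected=dose_gy, volume_cc=volume_cc(mask)))
        return DoseGrid(dose_vals, spacing), lesions

    def test_all_responders_case_not_boost_eligible(self):
        dose, lesions = self._dose_and_lesions([("gtv_1", 400.0)])
        targets = build_boost_targets(lesions, dose)
        assert not targets.boost_eligible
        assert targets.boost_targets[0].reason == "responder"
        # the monotherapy plan still targets the lesion
        assert "gtv_1" in targets.alone_ptvs

    def test_fully_cold_lesion_boost_equals_alone_ptv(self):
        dose, lesions = self._dose_and_lesions([("gtv_1", 30.0)])
        targets = build_boost_targets(lesions, dose)
        t = targets.boost_targets[0]
        assert t.eligible
        np.testing.assert_array_equal(t.ptv.values,
                                      targets.alone_ptvs["gtv_1"].values)

    def test_two_lesion_case_selects_only_underdosed_subvolume(self, rng):
        dose, lesions = self._dose_and_lesions([("gtv_1", 400.0), ("gtv_2", 100.0)])
        # give lesion 2 mixed voxel doses around the 70 Gy threshold
        m2 = lesions[1].gtv.values
        dose.values[m2] = rng.uniform(20, 140, m2.sum())
        lesions[1] = Lesion("gtv_2", lesions[1].gtv, 100.0, 60.0,
                            lesions[1].volume_cc)
        targets = build_boost_targets(lesions, dose)
        eligible = [t for t in targets.boost_targets if t.eligible]
        assert [t.lesion_id for t in eligible] == ["gtv_2"]
        sub = eligible[0].boost_gtv
        assert 0 < sub.voxel_count < lesions[1].gtv.voxel_count
        assert np.all(lesions[1].gtv.values[sub.values])  # subvolume inside GTV
        assert np.all(eligible[0].ptv.values[sub.values])  # PTV contains it

    def test_covered_eligible_lesion_dropped_as_empty_subvolume(self):
        # mean dose below 292 but every voxel at/above 70 Gy
        dose, lesions = self._dose_and_lesions([("gtv_1", 150.0)])
        targets = build_boost_targets(lesions, dose)
        assert not targets.boost_eligible
        assert targets.boost_targets[0].reason == "empty-subvolume"

    def test_too_small_lesion_flagged_non_evaluable(self):
        dose, lesions = self._dose_and_lesions([("gtv_1", 30.0)])
        small = Lesion("gtv_1", lesions[0].gtv, 30.0, 30.0, volume_cc=1.5)
        targets = build_boost_targets([small], dose)
        assert targets.boost_targets[0].reason == "too-small"

    def test_selection_independent_of_lesion_order(self, rng):
        dose, lesions = self._dose_and_lesions(
            [("gtv_1", 400.0), ("gtv_2", 100.0), ("gtv_3", 30.0)])
        fwd = build_boost_targets(lesions, dose)
        rev = build_boost_targets(lesions[::-1], dose)
        assert {t.lesion_id: t.eligible for t in fwd.boost_targets} == \
               {t.lesion_id: t.eligible for t in rev.boost_targets}

    def test_lesion_from_mask_measures_metrics(self):
        dose, lesions = self._dose_and_lesions([("gtv_1", 100.0)])
        les = lesion_from_mask("gtv_1", lesions[0].gtv, dose)
        assert les.mean_dose_corrected == pytest.approx(100.0)
        assert les.d90_uncorrected == pytest.approx(100.0)
        assert les.volume_cc == pytest.approx(volume_cc(lesions[0].gtv))


class TestDebulkingStats:
    @pytest.mark.parametrize("alone, boost, expected", [
        (257.0, 59.0, 77.04),   # largest observed reduction
        (20.0, 20.0, 0.0),      # identical plans
        (200.0, 150.0, 25.0),
    ])
    def test_relative_reduction(self, alone, boost, expected):
        assert debulking_stats(alone, boost) == pytest.approx(expected, abs=0.01)

    def test_nonpositive_alone_volume_rejected(self):
        with pytest.raises(ValueError):
            debulking_stats(0.0, 0.0)
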