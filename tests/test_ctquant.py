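"""CT thresholding, HU-range estimation, false-positive removal, accounting."""

import numpy as np
import pytest

import turtlebis as tb
from turtlebis.ctquant import (DEFAULT_HU_RANGE, CTVolume, HURange, quantify,
                               remove_false_positives, threshold_segment)
from turtlebis.errors import ArgumentError, ConsistencyError


def _flat_volume(value, shape=(4, 4, 4), **geom):
    geom = {"in_plane_spacing": 1.0, "slice_spacing": 0.625,
            "slice_thickness": 1.25, **geom}
    return CTVolume(hu=np.full(shape, value, np.int16), **geom)


class TestThreshold:
    def test_threshold_inclusive_on_both_bounds(self):
        hu = np.array([[[-33, -32, 0, 10, 11]]], np.int16)
        vol = CTVolume(hu, 1.0, 0.625, 1.25)
        mask = threshold_segment(vol, HURange(-32, 10))
        assert mask.tolist() == [[[False, True, True, True, False]]]

    def test_range_outside_data_gives_empty_mask(self, default_phantom):
        vol, _ = default_phantom
        assert threshold_segment(vol, HURange(2500, 3000)).sum() == 0

    def test_saturating_range_selects_everything(self, default_phantom):
        vol, _ = default_phantom
        assert threshold_segment(vol, HURange(-1024, 3071)).all()

    def test_candidate_is_adipose_plus_in_range_false_positives(self, default_phantom):
        vol, truth = default_phantom
        rng_ = HURange(-32.2, 10.1)
        cand = threshold_segment(vol, rng_)
        in_range = (vol.hu >= rng_.hu_min) & (vol.hu <= rng_.hu_max)
        expected = truth.adipose_mask.copy()
        for m in truth.class_masks.values():
            expected |= m & in_range
        assert np.array_equal(cand, expected)

    def test_widening_range_never_shrinks_candidate(self, default_phantom):
        vol, _ = default_phantom
        sizes = [threshold_segment(vol, HURange(-20 - w, 5 + w)).sum()
                 for w in (0, 5, 12, 40, 300)]
        assert sizes == sorted(sizes)


class TestHURangeEstimation:
    def test_estimated_range_covers_adipose_mode(self):
        hm = tb.synthetic.HUModel()
        hm.adipose = tb.synthetic.TissueHU(-15.0, 8.0, -40.0, 10.0)
        vol, truth = tb.build_phantom(tb.PhantomSpec(seed=5, hu_model=hm))
        est = tb.estimate_hu_range(vol, truth.body_mask)
        assert not est.fallback
        vals = vol.hu[truth.adipose_mask]
        coverage = ((vals >= est.hu_min) & (vals <= est.hu_max)).mean()
        assert coverage >= 0.95

    def test_single_tissue_falls_back_to_printed_range(self):
        vol = _flat_volume(40, shape=(32, 32, 32))
        est = tb.estimate_hu_range(vol, np.ones(vol.hu.shape, bool))
        assert est.fallback
        assert (est.hu_min, est.hu_max) == (DEFAULT_HU_RANGE.hu_min,
                                            DEFAULT_HU_RANGE.hu_max)

    def test_empty_body_mask_rejected(self):
        vol = _flat_volume(40)
        with pytest.raises(ArgumentError):
            tb.estimate_hu_range(vol, np.zeros(vol.hu.shape, bool))

    def test_hu_range_type_invariant(self):
        with pytest.raises(ArgumentError):
            HURange(10, 10)


class TestFalsePositiveRemoval:
    def test_oracle_recovers_truth_exactly(self, default_phantom):
        vol, truth = default_phantom
        cand = threshold_segment(vol, HURange(-32.2, 10.1))
        masks = remove_false_positives(cand, vol, mode="oracle", truth=truth)
        assert np.array_equal(masks.final_adipose, truth.adipose_mask)

    def test_oracle_without_truth_rejected(self, default_phantom):
        vol, _ = default_phantom
        cand = threshold_segment(vol, HURange(-32.2, 10.1))
        with pytest.raises(ArgumentError):
            remove_false_positives(cand, vol, mode="oracle")

    def test_rules_remove_table_with_high_dice(self):
        vol, truth = tb.build_phantom(tb.PhantomSpec(
            seed=9, fp_plan=frozenset({"table"})))
        cand = threshold_segment(vol, HURange(-32.2, 10.1))
        masks = remove_false_positives(cand, vol, mode="rules")
        removed = masks.removed["table"]
        table = truth.class_masks["table"]
        dice = 2 * (removed & table).sum() / (removed.sum() + table.sum())
        assert dice >= 0.99
        assert np.array_equal(masks.final_adipose, truth.adipose_mask)

    def test_rules_noop_without_false_positives(self):
        vol, truth = tb.build_phantom(tb.PhantomSpec(
            grid_shape=(48, 48, 48), fp_plan=frozenset(), seed=11))
        cand = threshold_segment(vol, HURange(-32.2, 10.1))
        masks = remove_false_positives(cand, vol, mode="rules")
        assert np.array_equal(masks.final_adipose, cand)

    def test_rules_keep_all_true_adipose(self, default_phantom):
        # B/D/table rules must not eat into the depots; A and C stay (they
        # need the oracle)
        vol, truth = default_phantom
        cand = threshold_segment(vol, HURange(-32.2, 10.1))
        masks = remove_false_positives(cand, vol, mode="rules",
                                       git_region=truth.class_masks["D"])
        assert not (truth.adipose_mask & ~masks.final_adipose).any()
        kept_fp = masks.final_adipose & ~truth.adipose_mask
        ac = truth.class_masks["A"] | truth.class_masks["C"]
        assert not (kept_fp & ~ac).any()

    def test_unknown_mode_rejected(self, default_phantom):
        vol, _ = default_phantom
        with pytest.raises(ArgumentError):
            remove_false_positives(np.zeros(vol.hu.shape, bool), vol, mode="cnn")

    def test_mask_set_consistency_enforced(self):
        cand = np.ones((3, 3, 3), bool)
        with pytest.raises(ConsistencyError):
            tb.SegmentationMaskSet(candidate=cand, removed={},
                                   final_adipose=np.zeros((3, 3, 3), bool))


class TestQuantify:
    def _masks(self, final, candidate=None):
        candidate = final if candidate is None else candidate
        return tb.SegmentationMaskSet(candidate=candidate, removed={},
                                      final_adipose=final)

    def test_voxel_volume_arithmetic(self):
        # 1000 voxels at 0.5 mm in-plane, 0.625 mm slice spacing
        shape = (10, 10, 10)
        vol = _flat_volume(-15, shape, in_plane_spacing=0.5)
        final = np.ones(shape, bool)
        est = quantify(self._masks(final), np.ones(shape, bool), vol, 10.0)
        assert est.at_volume_cm3 == pytest.approx(1000 * 0.15625 / 1000)

    def test_fraction_to_mass_arithmetic(self):
        shape = (10, 10, 10)
        vol = _flat_volume(-15, shape)
        body = np.ones(shape, bool)
        final = np.zeros(shape, bool)
        final.ravel()[:65] = True  # 65/1000 voxels
        est = quantify(self._masks(final), body, vol, 10.0)
        assert est.at_fraction == pytest.approx(0.065)
        assert est.at_mass_kg == pytest.approx(0.65)
        assert est.nonat_mass_kg == pytest.approx(9.35)

    def test_empty_adipose_conserves_mass(self):
        shape = (8, 8, 8)
        vol = _flat_volume(40, shape)
        est = quantify(self._masks(np.zeros(shape, bool)),
                       np.ones(shape, bool), vol, 7.3)
        assert est.at_mass_kg == 0.0
        assert est.nonat_mass_kg == 7.3

    def test_mass_conservation_random_masks(self, rng):
        shape = (12, 12, 12)
        vol = _flat_volume(-10, shape)
        body = np.ones(shape, bool)
        for _ in range(25):
            final = rng.random(shape) < rng.uniform(0, 0.4)
            mass = float(rng.uniform(0.5, 40))
            est = quantify(self._masks(final), body, vol, mass)
            assert est.at_mass_kg + est.nonat_mass_kg == mass

    def test_adipose_outside_body_rejected(self):
        shape = (8, 8, 8)
        vol = _flat_volume(-10, shape)
        body = np.zeros(shape, bool)
        body[:4] = True
        final = np.ones(shape, bool)
        with pytest.raises(ConsistencyError):
            quantify(self._masks(final), body, vol, 5.0)

    def test_body_volume_matches_per_slice_summation(self, default_phantom):
        vol, truth = default_phantom
        est = quantify(self._masks(truth.adipose_mask), truth.body_mask, vol, 10.0)
        # independent accounting: per-slice area in mm^2 times slice spacing
        per_slice = sum(
            truth.body_mask[k].sum() * vol.in_plane_spacing ** 2
            for k in range(truth.body_mask.shape[0])
        ) * vol.slice_spacing / 1000.0
        assert est.body_volume_cm3 == pytest.approx(per_slice)

    def test_oracle_end_to_end_fraction_exact(self, default_phantom):
        vol, truth = default_phantom
        cand = threshold_segment(vol, HURange(-32.2, 10.1))
        masks = remove_false_positives(cand, vol, mode="oracle", truth=truth)
        est = quantify(masks, truth.body_mask, vol, 12.0)
        assert est.at_fraction == truth.true_at_fraction_voxelized


class TestVolumeIO:
    def test_nifti_round_trip(self, tmp_path):
        vol, _ = tb.build_phantom(tb.PhantomSpec(grid_shape=(32, 32, 32), seed=2))
        path = tmp_path / "ct.nii.gz"
        tb.write_volume(vol, path)
        back = tb.read_volume(path)
        assert np.array_equal(back.hu, vol.hu)
        assert back.in_plane_spacing == pytest.approx(vol.in_plane_spacing)
        assert back.slice_spacing == pytest.approx(vol.slice_spacing)
        assert back.slice_thickness == pytest.approx(vol.slice_thickness)

    def test_mask_label_round_trip(self, tmp_path):
        from turtlebis.ctquant import read_mask_labels, write_mask_labels
        vol, truth = tb.build_phantom(tb.PhantomSpec(grid_shape=(32, 32, 32), seed=2))
        path = tmp_path / "labels.nii.gz"
        write_mask_labels(truth, vol, path)
        masks = read_mask_labels(path)
        assert np.array_equal(masks["adipose"], truth.adipose_mask)
        assert np.array_equal(masks["table"], truth.class_masks["table"])

    def test_hu_bounds_enforced(self):
        with pytest.raises(ArgumentError):
            CTVolume(np.full((2, 2, 2), 5000, np.int16), 1.0, 0.625, 1.25)
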