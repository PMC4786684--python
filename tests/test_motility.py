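import numpy as np
import pytest

from gliaquant.motility import (
    ChangeMap,
    Label,
    analyze_movie,
    classify_changes,
    instability_index,
    motility_index,
    stability_histogram,
    stability_index,
    traced_motility,
    TracedProcessSeries,
)
from gliaquant import synthetic as syn
from oracles import classify_counts_bruteforce


def _maps_from_masks(masks):
    return [classify_changes(masks[i], masks[i + 1], interval_index=i) for i in range(len(masks) - 1)]


class TestClassifyChanges:
    def test_identical_masks_all_stable(self, rng):
        m = rng.random((8, 8)) < 0.5
        cm = classify_changes(m, m)
        assert cm.counts["stable"] == int(m.sum())
        assert cm.counts["extended"] == cm.counts["retracted"] == 0

    def test_appearing_foreground_is_extension(self):
        m2 = np.zeros((5, 5), bool)
        m2[1:3, 1:3] = True
        cm = classify_changes(np.zeros((5, 5), bool), m2)
        assert cm.counts["extended"] == 4

    def test_counts_match_bruteforce_enumeration(self, random_mask_pair):
        for _ in range(25):
            m1, m2 = random_mask_pair((3, 3))
            assert classify_changes(m1, m2).counts == classify_counts_bruteforce(m1, m2)

    def test_label_conservation_partitions_each_frame(self, random_mask_pair):
        m1, m2 = random_mask_pair((16, 16))
        cm = classify_changes(m1, m2)
        assert cm.counts["stable"] + cm.counts["extended"] == int(m2.sum())
        assert cm.counts["stable"] + cm.counts["retracted"] == int(m1.sum())

    def test_swapping_frames_exchanges_extension_and_retraction(self, random_mask_pair):
        m1, m2 = random_mask_pair((12, 12))
        fwd, rev = classify_changes(m1, m2).counts, classify_changes(m2, m1).counts
        assert fwd["extended"] == rev["retracted"]
        assert fwd["retracted"] == rev["extended"]
        assert fwd["stable"] == rev["stable"]

    def test_validity_mask_excludes_pixels_from_counts(self):
        m1 = np.ones((4, 4), bool)
        valid = np.zeros((4, 4), bool)
        valid[:2] = True
        cm = classify_changes(m1, m1, validity=valid)
        assert cm.counts["stable"] == 8

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            classify_changes(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestMotilityIndex:
    def test_all_stable_gives_zero(self):
        m = np.ones((6, 6), bool)
        res = motility_index(_maps_from_masks([m, m, m]))
        assert res.motility_index == 0.0

    def test_formula_on_constructed_counts(self):
        # ext=2, ret=3, stable=5 -> motility 1.0, extension 0.4, retraction 0.6
        m1 = np.zeros((4, 4), bool)
        m1.ravel()[:8] = True  # 5 stable + 3 retracted
        m2 = np.zeros((4, 4), bool)
        m2.ravel()[:5] = True
        m2.ravel()[8:10] = True  # 2 extended
        res = motility_index([classify_changes(m1, m2)])
        assert res.motility_index == pytest.approx(1.0)
        assert res.extension_index == pytest.approx(0.4)
        assert res.retraction_index == pytest.approx(0.6)

    def test_extension_plus_retraction_equals_motility(self, random_mask_pair):
        m1, m2 = random_mask_pair((16, 16), p=0.6)
        maps = [classify_changes(m1, m2)]
        res = motility_index(maps)
        assert res.extension_index + res.retraction_index == pytest.approx(res.motility_index)

    def test_zero_stable_interval_raises_naming_interval(self):
        m1 = np.zeros((4, 4), bool)
        m1[0, 0] = True
        m2 = np.zeros((4, 4), bool)
        m2[3, 3] = True
        with pytest.raises(ValueError, match="interval 0"):
            motility_index([classify_changes(m1, m2, interval_index=0)])

    def test_planted_fraction_recovery_noiseless_is_exact(self):
        arb = syn.generate_arbor(6, [5, 10, 15, 20], seed=1)
        tl = syn.generate_timelapse(
            arb, T=12, extension_fraction=0.1, retraction_fraction=0.1, seed=2
        )
        res, _ = analyze_movie(tl.frames, register=True)
        truth = motility_index(_maps_from_masks(tl.masks))
        assert res.motility_index == pytest.approx(truth.motility_index, abs=0)
        assert res.extension_index == pytest.approx(truth.extension_index, abs=0)


class TestStabilityIndices:
    def _overlays(self, seq):
        """Build overlays from a sequence of 1D foreground tuples."""
        masks = []
        for fg in seq:
            m = np.zeros((1, 16), bool)
            m[0, list(fg)] = True
            masks.append(m)
        return _maps_from_masks(masks)

    def test_all_extended_persist(self):
        maps = self._overlays([(0, 1), (0, 1, 2, 3), (0, 1, 2, 3)])
        assert stability_index(maps[0], maps[1]) == 1.0

    def test_no_extended_persist(self):
        maps = self._overlays([(0, 1), (0, 1, 2, 3), (0, 1)])
        assert stability_index(maps[0], maps[1]) == 0.0

    def test_fractional_stability(self):
        # 10 extended pixels, 4 survive into the next overlay
        base = (0,)
        ext = tuple(range(1, 11))
        keep = tuple(range(1, 5))
        maps = self._overlays([base, base + ext, base + keep])
        assert stability_index(maps[0], maps[1]) == pytest.approx(0.4)

    def test_undefined_stability_is_nan_not_zero(self):
        maps = self._overlays([(0, 1), (0, 1), (0, 1)])
        assert np.isnan(stability_index(maps[0], maps[1]))

    def test_instability_fraction(self):
        # 12 stable pixels, 3 retract in the next overlay
        stable = tuple(range(12))
        maps = self._overlays([stable, stable, tuple(range(9))])
        assert instability_index(maps[0], maps[1]) == pytest.approx(0.25)

    def test_instability_extremes(self):
        stable = tuple(range(5))
        maps = self._overlays([stable, stable, stable])
        assert instability_index(maps[0], maps[1]) == 0.0
        maps = self._overlays([stable, stable, ()])
        assert instability_index(maps[0], maps[1]) == 1.0


class TestStabilityHistogram:
    def _masks(self, rows):
        return [np.array([row], dtype=bool) for row in rows]

    def test_persistent_pixel_contributes_one_at_every_offset(self):
        # pixel 1 extends in overlay 0, stabilizes at overlay 1, persists
        rows = [
            [1, 0, 0, 0],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
        ]
        hist = stability_histogram(_maps_from_masks(self._masks(rows)))
        assert hist == [1.0, 1.0, 1.0]

    def test_immediately_retracting_pixel_drops_to_zero(self):
        rows = [
            [1, 0],
            [1, 1],
            [1, 1],  # stabilized at overlay 1
            [1, 0],  # retracted at overlay 2
            [1, 0],
        ]
        hist = stability_histogram(_maps_from_masks(self._masks(rows)))
        assert hist[0] == 1.0
        assert hist[1] == 0.0

    def test_planted_half_surviving_cohort(self):
        # two pixels stabilize together; one persists one extra overlay
        rows = [
            [1, 0, 0],
            [1, 1, 1],
            [1, 1, 1],  # both stable (stabilization overlay)
            [1, 1, 0],  # pixel 2 retracts
            [1, 1, 0],
        ]
        hist = stability_histogram(_maps_from_masks(self._masks(rows)))
        assert hist[0] == 1.0
        assert hist[1] == pytest.approx(0.5)

    def test_always_stable_pixels_excluded(self):
        rows = [[1, 1]] * 5
        hist = stability_histogram(_maps_from_masks(self._masks(rows)))
        assert hist == []

    def test_too_few_overlays_raise(self):
        with pytest.raises(ValueError):
            stability_histogram(_maps_from_masks(self._masks([[1], [1], [1]])))


class TestTracedMotility:
    def test_constant_length_is_zero(self):
        assert traced_motility(TracedProcessSeries("p", [10, 10, 10], 5.0)) == 0.0

    def test_formula(self):
        assert traced_motility(TracedProcessSeries("p", [10, 15], 5.0)) == pytest.approx(1.0)
        assert traced_motility(TracedProcessSeries("p", [10, 12, 9], 5.0)) == pytest.approx(0.5)

    def test_single_timepoint_raises(self):
        with pytest.raises(ValueError):
            traced_motility(TracedProcessSeries("p", [10.0], 5.0))
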