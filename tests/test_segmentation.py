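"""Threshold selection, binarization, overlap resolution and morphology."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fundusdr import (
    InvalidInputError,
    ProbabilityMaps,
    ThresholdSet,
    binarize,
    postprocess,
    resolve_overlaps,
    segment_image,
    select_threshold,
)
from fundusdr.segmentation import (
    closing,
    dilate,
    erode,
    opening,
    remove_small_components,
)


from oracles import dilation_oracle, erosion_oracle, youden_sweep_oracle


def maps_from(p_e, p_h, p_m):
    arr = np.stack([p_e, p_h, p_m])
    return ProbabilityMaps(
        p_exudate=arr[0], p_hemorrhage=arr[1], p_microaneurysm=arr[2],
        p_background=np.clip(1 - arr.sum(axis=0), 0, 1),
    )


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

class TestSelectThreshold:
    def test_perfect_separation(self):
        scores = np.array([0.9] * 30 + [0.1] * 70)
        truth = np.array([True] * 30 + [False] * 70)
        th, record = select_threshold(scores, truth)
        assert 0.1 < th <= 0.9
        assert record["sensitivity"] == 1.0 and record["specificity"] == 1.0

    def test_matches_exhaustive_sweep_oracle(self, rng):
        for _ in range(5):
            scores = np.concatenate([
                rng.beta(5, 2, 60),   # positives score high
                rng.beta(2, 5, 140),  # negatives score low
            ])
            truth = np.array([True] * 60 + [False] * 140)
            th, record = select_threshold(scores, truth)
            oracle_th, oracle_j = youden_sweep_oracle(scores, truth)
            assert th == pytest.approx(oracle_th, abs=1e-12)
            assert record["value"] == pytest.approx(oracle_j, abs=1e-9)

    def test_single_class_truth_rejected(self):
        with pytest.raises(InvalidInputError):
            select_threshold(np.array([0.1, 0.9]), np.array([True, True]))

    def test_identical_scores_degenerate_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            th, record = select_threshold(
                np.full(10, 0.5), np.array([True] * 5 + [False] * 5)
            )
        assert record["degenerate"]

    def test_closest_corner_criterion_available(self, rng):
        scores = np.concatenate([rng.beta(4, 2, 50), rng.beta(2, 4, 50)])
        truth = np.array([True] * 50 + [False] * 50)
        th, record = select_threshold(scores, truth, criterion="closest")
        assert 0 < th < 1 and record["criterion"] == "closest"


class TestBinarize:
    def test_all_zero_map(self):
        assert not binarize(np.zeros((5, 5)), 0.5).any()

    def test_boundary_is_inclusive(self):
        out = binarize(np.full((3, 3), 0.4), 0.4)
        assert out.all()

    def test_elementwise_oracle(self, rng):
        m = rng.random((20, 20))
        th = 0.37
        assert binarize(m, th).sum() == sum(v >= th for v in m.ravel())

    def test_monotonicity_in_threshold(self, rng):
        m = rng.random((30, 30))
        counts = [binarize(m, th).sum() for th in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold(self):
        with pytest.raises(InvalidInputError):
            binarize(np.zeros((2, 2)), 0.0)


class TestResolveOverlaps:
    def test_disjoint_inputs_unchanged(self, rng):
        p = rng.random((3, 10, 10))
        b_e = np.zeros((10, 10), bool); b_e[:3] = True
        b_h = np.zeros((10, 10), bool); b_h[5:7] = True
        b_m = np.zeros((10, 10), bool); b_m[9:] = True
        maps = maps_from(*p)
        labels = resolve_overlaps(
            maps, {"exudate": b_e, "hemorrhage": b_h, "microaneurysm": b_m}
        )
        assert np.array_equal(labels == 1, b_e)
        assert np.array_equal(labels == 2, b_h)
        assert np.array_equal(labels == 3, b_m)

    def test_higher_probability_wins(self):
        p_e = np.full((1, 1), 0.9)
        p_h = np.full((1, 1), 0.8)
        p_m = np.zeros((1, 1))
        maps = maps_from(p_e, p_h, p_m)
        ones = np.ones((1, 1), bool)
        labels = resolve_overlaps(
            maps, {"exudate": ones, "hemorrhage": ones, "microaneurysm": ~ones}
        )
        assert labels[0, 0] == 1

    def test_exact_tie_uses_priority(self):
        half = np.full((1, 1), 0.5)
        maps = maps_from(half.copy(), half.copy(), half.copy())
        ones = np.ones((1, 1), bool)
        labels = resolve_overlaps(
            maps, {"exudate": ones, "hemorrhage": ones, "microaneurysm": ones}
        )
        assert labels[0, 0] == 1  # exudate > hemorrhage > microaneurysm

    def test_per_pixel_argmax_oracle(self, rng):
        p = rng.random((3, 15, 15))
        b = rng.random((3, 15, 15)) > 0.5
        maps = maps_from(*p)
        labels = resolve_overlaps(
            maps, {"exudate": b[0], "hemorrhage": b[1], "microaneurysm": b[2]}
        )
        for r in range(15):
            for c in range(15):
                cands = [k for k in range(3) if b[k, r, c]]
                if not cands:
                    assert labels[r, c] == 0
                else:
                    best = max(cands, key=lambda k: (p[k, r, c], -k))
                    assert labels[r, c] == best + 1

    def test_shape_mismatch_rejected(self, rng):
        maps = maps_from(*rng.random((3, 5, 5)))
        bad = {"exudate": np.zeros((4, 4), bool),
               "hemorrhage": np.zeros((5, 5), bool),
               "microaneurysm": np.zeros((5, 5), bool)}
        with pytest.raises(InvalidInputError):
            resolve_overlaps(maps, bad)


# ---------------------------------------------------------------------------
# morphology and area rule
# ---------------------------------------------------------------------------

class TestMorphology:
    @pytest.mark.parametrize("size,center", [(5, (2, 2)), (4, (1, 1))])
    def test_erosion_matches_set_oracle(self, rng, size, center):
        mask = rng.random((24, 24)) > 0.35
        assert np.array_equal(erode(mask, size), erosion_oracle(mask, size, center))

    def test_dilation_matches_set_oracle(self, rng):
        mask = rng.random((20, 20)) > 0.8
        assert np.array_equal(dilate(mask, 5), dilation_oracle(mask, 5, (2, 2)))

    def test_closing_opening_match_composed_oracle(self, rng):
        mask = rng.random((30, 30)) > 0.6
        dil = dilation_oracle(mask, 5, (2, 2))
        assert np.array_equal(closing(mask, 5), erosion_oracle(dil, 5, (2, 2)))
        ero = erosion_oracle(mask, 5, (2, 2))
        assert np.array_equal(opening(mask, 5), dilation_oracle(ero, 5, (2, 2)))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(hnp.arrays(bool, (32, 32)))
    def test_opening_closing_idempotent(self, core):
        # content kept away from the frame so border clipping cannot interfere
        mask = np.zeros((48, 48), bool)
        mask[8:40, 8:40] = core
        assert np.array_equal(opening(opening(mask, 5), 5), opening(mask, 5))
        assert np.array_equal(closing(closing(mask, 5), 5), closing(mask, 5))

    def test_solid_square_survives_postprocess(self):
        mask = np.zeros((100, 100), bool)
        mask[20:80, 20:80] = True  # 60x60 = 3600 px >= 625
        out = postprocess(mask, patch_size=50)
        assert out.sum() >= 625
        # the survivor equals the brute-force composition of the three ops
        step = erosion_oracle(dilation_oracle(mask, 5, (2, 2)), 5, (2, 2))
        step = dilation_oracle(erosion_oracle(step, 5, (2, 2)), 5, (2, 2))
        step = erosion_oracle(step, 4, (1, 1))
        assert np.array_equal(out, step)  # 3249 px, passes the area rule

    def test_small_blob_removed_by_area_rule(self):
        mask = np.zeros((100, 100), bool)
        mask[40:60, 40:60] = True  # 400 px after morphology shrink < 625
        assert not postprocess(mask, patch_size=50).any()

    def test_empty_map_stays_empty(self):
        assert not postprocess(np.zeros((30, 30), bool), 50).any()

    def test_no_surviving_component_below_area_rule(self, rng):
        mask = rng.random((120, 120)) > 0.45
        out = postprocess(mask, patch_size=50)
        from skimage import measure

        labels = measure.label(out, connectivity=2)
        if labels.max():
            areas = np.bincount(labels.ravel())[1:]
            assert areas.min() >= 625

    def test_area_rule_exact_boundary(self):
        # remove_small_components keeps exactly area >= S^2/4
        mask = np.zeros((60, 60), bool)
        mask[0:25, 0:25] = True
        assert remove_small_components(mask, 625).any()
        mask2 = np.zeros((60, 60), bool)
        mask2[0:24, 0:26] = True  # 624 px
        assert not remove_small_components(mask2, 625).any()


class TestSegmentImage:
    def test_background_maps_give_empty_segmentation(self):
        z = np.zeros((40, 40))
        maps = maps_from(z, z, z)
        ths = ThresholdSet({"exudate": 0.5, "hemorrhage": 0.5, "microaneurysm": 0.5})
        seg = segment_image(maps, ths, patch_size=50)
        assert not seg.label_map.any()

    def test_shared_region_yields_single_sign(self):
        base = np.zeros((80, 80))
        base[10:70, 10:70] = 0.9
        maps = maps_from(base.copy(), base * 0.95, base * 0.9)
        ths = ThresholdSet({"exudate": 0.5, "hemorrhage": 0.5, "microaneurysm": 0.5})
        seg = segment_image(maps, ths, patch_size=50)
        masks = seg.per_sign_masks
        assert masks["exudate"].any()
        assert not masks["hemorrhage"].any() and not masks["microaneurysm"].any()

    def test_masks_pairwise_disjoint(self, rng):
        p = rng.random((3, 90, 90))
        maps = maps_from(*p)
        ths = ThresholdSet({"exudate": 0.6, "hemorrhage": 0.6, "microaneurysm": 0.6})
        seg = segment_image(maps, ths, patch_size=20)
        m = seg.per_sign_masks
        assert not (m["exudate"] & m["hemorrhage"]).any()
        assert not (m["exudate"] & m["microaneurysm"]).any()
        assert not (m["hemorrhage"] & m["microaneurysm"]).any()

    def test_threshold_set_validation(self):
        with pytest.raises(InvalidInputError):
            ThresholdSet({"exudate": 1.0, "hemorrhage": 0.5, "microaneurysm": 0.5})

    def test_threshold_round_trip(self, tmp_path):
        ths = ThresholdSet({"exudate": 0.7, "hemorrhage": 0.5, "microaneurysm": 0.4},
                           {"exudate": {"value": 0.9}})
        path = tmp_path / "th.json"
        ths.save(path)
        again = ThresholdSet.load(path)
        assert again.thresholds == ths.thresholds
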