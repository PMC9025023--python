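import math

import numpy as np
import pytest

from pearlseg import concavity, metrics, preprocess, regions
from pearlseg.concavity import UnsplittableRegionError
from pearlseg.config import RunConfig
from pearlseg.synth import SceneSpec, generate_scene


class TestVertexAngle:
    @pytest.mark.parametrize(
        "prev,at,nxt,expected",
        [
            ((0, 0), (2, 0), (4, 0), 180.0),
            ((0, 0), (2, 0), (2, 2), 90.0),
            ((0, 0), (2, 0), (1, math.sqrt(3)), 60.0),
        ],
    )
    def test_known_triangles(self, prev, at, nxt, expected):
        assert concavity.vertex_angle(prev, at, nxt) == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            concavity.vertex_angle((1, 1), (1, 1), (2, 2))

    def test_law_of_cosines_equals_vector_formulation(self):
        """Angle model vs an independent two-vector arccos oracle."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            p_prev, p, p_next = rng.integers(-50, 51, (3, 2))
            if np.array_equal(p_prev, p) or np.array_equal(p_next, p):
                continue
            u = p_prev - p
            v = p_next - p
            cos_t = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            oracle = math.degrees(math.acos(max(-1.0, min(1.0, cos_t))))
            assert concavity.vertex_angle(p_prev, p, p_next) == pytest.approx(
                oracle, abs=1e-9
            )
            checked += 1


class TestDetectCandidates:
    def test_smooth_circle_has_no_candidates(self, make_disc):
        c = regions.trace_contour(make_disc((80, 80), (40, 40), 30))
        assert not any(p.is_candidate for p in concavity.detect_candidates(c))

    def test_square_corners_are_not_pits(self):
        m = np.zeros((40, 40), dtype=bool)
        m[10:30, 10:30] = True
        c = regions.trace_contour(m)
        pts = concavity.detect_candidates(c, step=2, angle_threshold_deg=59.9)
        assert not any(p.is_candidate for p in pts)

    def test_tangent_discs_yield_two_pit_candidates(self, tangent_discs_mask):
        c = regions.trace_contour(tangent_discs_mask)
        cands = [p for p in concavity.detect_candidates(c) if p.is_candidate]
        assert len(cands) == 2
        for p in cands:  # true tangency at (50, 80)
            assert np.hypot(p.point[0] - 50, p.point[1] - 80) <= 3

    def test_short_contour_rejected(self):
        with pytest.raises(ValueError):
            concavity.detect_candidates(np.array([[0, 0], [0, 1], [1, 1]]), step=2)


def _contact_region(img, cfg=None):
    cfg = cfg or RunConfig()
    eq = preprocess.equalize_histogram(img)
    smu = preprocess.as_uint8(preprocess.gaussian_smooth(eq, cfg.sigma))
    t = preprocess.otsu_threshold(smu)
    mask = preprocess.morphological_clean(
        preprocess.binarize_otsu(smu, threshold=t), cfg.element_length
    )
    rt = regions.select_contact_regions(regions.area_ratios(regions.label_connected(mask)))
    lbl = rt.table.loc[rt.table["is_contact"], "label"].iloc[0]
    region = rt.labels == lbl
    return smu, t, mask, region


class TestMatchPits:
    def test_tangent_pair_accepts_one_pitpair(self, pair_scene):
        img, truth = pair_scene
        smu, t, _, region = _contact_region(img)
        contour = regions.trace_contour(region)
        pairs = concavity.match_pits(None, contour, smu, region, threshold=t)
        assert len(pairs) == 1
        mid = np.array(pairs[0].midpoint)
        tp = np.array(truth.contacts[0]["point"])
        assert np.linalg.norm(mid - tp) <= 3

    def test_background_gap_rejects_pairing(self):
        """Two discs separated by background, artificially bridged in the
        mask: the bisector samples background gray, so no pair is valid."""
        gray = np.full((100, 190), 230, dtype=np.uint8)
        rr, cc = np.mgrid[0:100, 0:190]
        d1 = (rr - 50) ** 2 + (cc - 50) ** 2 <= 30 * 30
        d2 = (rr - 50) ** 2 + (cc - 114) ** 2 <= 30 * 30  # 4-px gap
        gray[d1 | d2] = 25
        region = d1 | d2
        region[48:53, 79:86] = True  # fake bridge in the mask only
        contour = regions.trace_contour(region)
        with pytest.raises(UnsplittableRegionError):
            concavity.match_pits(None, contour, gray, region, threshold=128)

    def test_three_collinear_discs_give_two_pairs(self):
        spec = SceneSpec(
            clusters=(3, 1), grades="A1", axis_ratio=1.0,
            contact_angles=[[0.0, 0.0], []], seed=5,
        )
        img, truth = generate_scene(spec)
        smu, t, _, region = _contact_region(img)
        contour = regions.trace_contour(region)
        pairs = concavity.match_pits(None, contour, smu, region, threshold=t)
        assert len(pairs) == 2
        mids = sorted((np.array(p.midpoint) for p in pairs), key=lambda m: m[1])
        tps = sorted((np.array(c["point"]) for c in truth.contacts), key=lambda m: m[1])
        for mid, tp in zip(mids, tps):
            assert np.linalg.norm(mid - tp) <= 4


class TestSplitRegion:
    def test_empty_pair_list_is_noop(self, tangent_discs_mask):
        out = concavity.split_region(tangent_discs_mask, [])
        assert np.array_equal(out, tangent_discs_mask)

    def test_pixel_conservation(self, pair_scene):
        img, _ = pair_scene
        smu, t, mask, region = _contact_region(img)
        contour = regions.trace_contour(region)
        pairs = concavity.match_pits(None, contour, smu, region, threshold=t)
        out = concavity.split_region(mask, pairs)
        cut = np.concatenate(
            [np.column_stack(concavity._supercover_line(p.a, p.b)) for p in pairs]
        )
        n_cut = len(np.unique(cut, axis=0))
        assert mask.sum() - out.sum() == n_cut

    def test_split_separates_tangent_pair(self, pair_scene):
        from skimage import measure

        img, _ = pair_scene
        smu, t, mask, region = _contact_region(img)
        contour = regions.trace_contour(region)
        pairs = concavity.match_pits(None, contour, smu, region, threshold=t)
        before = measure.label(region, connectivity=2).max()
        after = measure.label(concavity.split_region(region, pairs), connectivity=2).max()
        assert (before, after) == (1, 2)


class TestSegmentScene:
    def test_isolated_discs_pass_through(self):
        spec = SceneSpec(clusters=(1, 1, 1), grades="A1", axis_ratio=1.0, seed=2)
        img, _ = generate_scene(spec)
        res = concavity.segment_scene(img)
        assert res.n_objects == 3
        assert res.pit_pairs == [] and res.unsplittable == []

    def test_batch_layout_recovers_all_objects(self):
        """Eight singles plus a 3-cluster and a 2-cluster: 13 objects out."""
        spec = SceneSpec(
            clusters=(3, 2) + (1,) * 8, grades="A2", seed=12, radius_spread=3.0
        )
        img, truth = generate_scene(spec)
        res = concavity.segment_scene(img)
        assert res.n_objects == 13
        ev = metrics.evaluate_segmentation(truth, res.labels, pre_split_mask=res.mask)
        assert ev.Y == 1.0

    def test_segmented_mask_triggers_no_further_splits(self, pair_scene):
        """Idempotence: the contact test finds nothing left to split in the
        mask segment_scene hands back."""
        img, _ = pair_scene
        res = concavity.segment_scene(img)
        rt = regions.select_contact_regions(
            regions.area_ratios(regions.label_connected(res.split_mask))
        )
        assert not rt.table["is_contact"].any()
        assert res.unsplittable == []

    def test_two_disc_split_areas_close_to_singles(self):
        spec = SceneSpec(
            clusters=(2, 1), grades="A1", axis_ratio=1.0,
            contact_angles=[[30.0], []], radius_px=30.0, radius_spread=0.0, seed=8,
        )
        img, truth = generate_scene(spec)
        res = concavity.segment_scene(img)
        assert res.n_objects == 3
        single = truth.table.set_index("label")
        ev = metrics.evaluate_segmentation(truth, res.labels, pre_split_mask=res.mask)
        for m in ev.matches.itertuples():
            true_area = single.loc[m.true_label, "area_px"]
            pred_area = res.table.set_index("label").loc[m.pred_label, "area_px"]
            assert abs(pred_area - true_area) / true_area <= 0.04
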