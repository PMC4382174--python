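"""Slide-scan segmentation, region filtering, and the stage transform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import ellipse

from wingspot import (
    RegionFilterRanges,
    SlideImage,
    StageTransform,
    filter_regions,
    from_stage_coords,
    generate_slide_image,
    locate_origin_and_axis,
    partition_acquisitions,
    segment_wings,
    to_stage_coords,
    trim_region,
)
from wingspot.slideprep import _region_stats


def ellipse_region(a=20, b=10, angle=0.0, shape=(120, 120)):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = ellipse(shape[0] // 2, shape[1] // 2, b, a, shape=shape, rotation=angle)
    mask[rr, cc] = True
    return _region_stats(mask, 1)


class TestSegmentWings:
    def test_uniform_bright_slide_has_no_regions(self):
        slide = SlideImage(np.full((60, 200), 230, dtype=np.uint8))
        assert segment_wings(slide) == []

    def test_fixture_wings_recovered_with_high_jaccard(self):
        img, outlines = generate_slide_image(3, seed=2)
        regions = segment_wings(SlideImage(img))
        assert len(regions) == 3
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        for region in regions:
            best = 0.0
            for o in outlines:
                true = o.contains(xx, yy)
                inter = (region.mask & true).sum()
                union = (region.mask | true).sum()
                best = max(best, inter / union)
            assert best >= 0.8


class TestFilterRegions:
    def test_circle_has_unit_aspect_and_is_kept(self):
        region = ellipse_region(a=12, b=12)
        assert region.aspect_ratio == pytest.approx(1.0, rel=0.03)
        kept, _ = filter_regions(
            [region], RegionFilterRanges(aspect=(0.8, 1.5), area_px=(10, 1e5))
        )
        assert len(kept) == 1

    def test_two_to_one_ellipse_aspect_is_four(self):
        region = ellipse_region(a=40, b=20, shape=(200, 200))
        assert region.aspect_ratio == pytest.approx(4.0, rel=0.02)

    def test_centroid_outside_lamella_discarded_with_position_reason(self):
        region = ellipse_region()
        ranges = RegionFilterRanges(
            aspect=(1.0, 10.0), area_px=(10, 1e5), centroid_x=(200, 300)
        )
        kept, discarded = filter_regions([region], ranges)
        assert not kept
        assert "position" in discarded[0][1]

    def test_degenerate_single_pixel_region_always_discarded(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5] = True
        region = _region_stats(mask, 1)
        _, discarded = filter_regions([region], RegionFilterRanges())
        assert "degenerate" in discarded[0][1]


class TestOriginAndTrim:
    def test_origin_found_near_true_hinge(self):
        img, outlines = generate_slide_image(1, seed=4)
        slide = SlideImage(img)
        (region,) = segment_wings(slide)
        region = locate_origin_and_axis(region, slide)
        err = math.dist(region.origin_xy, outlines[0].origin_xy)
        assert err <= 3.0

    def test_coincident_centroid_raises_degenerate_axis(self):
        region = ellipse_region(a=12, b=12)
        img = np.full((120, 120), 200.0)
        img[60, 60] = 255.0  # maximum exactly at the centroid
        with pytest.raises(ValueError, match="degenerate axis"):
            locate_origin_and_axis(region, SlideImage(img), blur_sigma_px=0)

    def test_trim_removes_near_origin_and_negative_side(self):
        region = ellipse_region(a=30, b=10, shape=(150, 150))
        region.origin_xy = (45.0, 75.0)  # left end of the major axis
        region.axis_xy = (1.0, 0.0)
        pitch = 84.7
        trimmed = trim_region(region, min_distance_um=10 * pitch, pixel_pitch_um=pitch)
        ys, xs = np.nonzero(trimmed.mask)
        assert (xs >= 45).all()                       # negative side removed
        assert ((xs - 45) ** 2 + (ys - 75) ** 2 >= 100).all()
        assert trimmed.area_px < region.area_px

    def test_min_distance_zero_and_positive_projection_keeps_mask(self):
        region = ellipse_region(a=20, b=10)
        region.origin_xy = (30.0, 60.0)
        region.axis_xy = (1.0, 0.0)
        trimmed = trim_region(region, min_distance_um=0.0, pixel_pitch_um=84.7)
        assert trimmed.area_px == region.area_px

    def test_full_trim_raises(self):
        region = ellipse_region(a=10, b=5)
        region.origin_xy = (60.0, 60.0)
        region.axis_xy = (1.0, 0.0)
        with pytest.raises(ValueError, match="fully trimmed"):
            trim_region(region, min_distance_um=1e6, pixel_pitch_um=84.7)


class TestPartition:
    def test_single_class_is_the_centroid(self):
        region = ellipse_region()
        (pos,) = partition_acquisitions(region, max_fields=6,
                                        reference_area_px=region.area_px * 10)
        assert pos[0] == pytest.approx(region.centroid_xy[0], abs=0.5)
        assert pos[1] == pytest.approx(region.centroid_xy[1], abs=0.5)

    def test_two_disjoint_blobs_split_at_their_centroids(self):
        mask = np.zeros((40, 120), dtype=bool)
        mask[15:25, 10:30] = True
        mask[15:25, 90:110] = True
        region = _region_stats(mask, 1)
        positions = partition_acquisitions(
            region, max_fields=6, reference_area_px=region.area_px * 3, seed=0
        )
        assert len(positions) == 2
        xs = sorted(p[0] for p in positions)
        assert xs[0] == pytest.approx(19.5, abs=0.5)
        assert xs[1] == pytest.approx(99.5, abs=0.5)

    def test_positions_lie_inside_the_mask_convex_hull(self):
        img, _ = generate_slide_image(4, seed=6)
        slide = SlideImage(img)
        for region in segment_wings(slide):
            region = locate_origin_and_axis(region, slide)
            trimmed = trim_region(region, pixel_pitch_um=slide.pixel_pitch_um)
            positions = partition_acquisitions(trimmed, max_fields=6, seed=0)
            ys, xs = np.nonzero(region.mask)
            from scipy.spatial import Delaunay

            hull = Delaunay(np.column_stack([xs, ys]))
            assert all(hull.find_simplex(p) >= 0 for p in positions)

    def test_partition_count_scales_with_area(self):
        region = ellipse_region(a=30, b=12, shape=(150, 150))
        ref = region.area_px
        assert len(partition_acquisitions(region, 6, reference_area_px=ref)) == 6
        assert len(partition_acquisitions(region, 6, reference_area_px=ref * 2)) == 3


class TestStageTransform:
    def test_center_maps_to_origin(self):
        t = StageTransform(center_xy=(10.0, 20.0), theta_rad=0.7, ratio=3.0)
        np.testing.assert_allclose(to_stage_coords((10.0, 20.0), t), (0.0, 0.0))

    def test_identity_rotation_is_pure_translation(self):
        t = StageTransform(center_xy=(5.0, 5.0), theta_rad=0.0, ratio=1.0)
        np.testing.assert_allclose(to_stage_coords((8.0, 2.0), t), (3.0, -3.0))

    def test_quarter_turn_with_doubling(self):
        t = StageTransform(center_xy=(0.0, 0.0), theta_rad=math.pi / 2, ratio=2.0)
        np.testing.assert_allclose(
            to_stage_coords((1.0, 0.0), t), (0.0, 2.0), atol=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
        st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
        st.floats(-math.pi, math.pi),
        st.floats(0.01, 100.0),
    )
    def test_distances_scale_by_exactly_r_and_roundtrip(self, ax, ay, bx, by, th, r):
        t = StageTransform(center_xy=(3.0, -7.0), theta_rad=th, ratio=r)
        A, B = np.array([ax, ay]), np.array([bx, by])
        Ap, Bp = to_stage_coords(A, t), to_stage_coords(B, t)
        d, dp = np.linalg.norm(A - B), np.linalg.norm(Ap - Bp)
        assert dp == pytest.approx(r * d, rel=1e-9, abs=1e-9)
        np.testing.assert_allclose(from_stage_coords(Ap, t), A, rtol=1e-9, atol=1e-6)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            StageTransform(center_xy=(0, 0), theta_rad=0.0, ratio=0.0)
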