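import numpy as np
import pytest
from shapely.geometry import Polygon, box

from scrubseg.errors import DimensionError, GeometryError
from scrubseg.geometry import (
    LabelMap,
    RasterScene,
    SegmentPolygon,
    outside_area,
    overlap_area,
    polygonize,
    rasterize,
)

from conftest import random_scene, ref_set, square
from oracles import pixel_overlap_area


def scene_of(rows, cols, res=1.0):
    return RasterScene(np.zeros((rows, cols, 3), dtype=np.uint8), res)


class TestRasterScene:
    def test_extent_consistent_with_grid(self):
        sc = scene_of(10, 20, 0.5)
        assert sc.plot_extent == (10.0, 5.0)

    def test_rejects_bad_resolution_and_values(self):
        with pytest.raises(Exception):
            RasterScene(np.zeros((4, 4, 3), dtype=np.uint8), 0.0)
        with pytest.raises(Exception):
            RasterScene(np.full((4, 4, 3), 300, dtype=np.int32), 1.0)

    def test_pixel_to_map_corner_convention(self):
        sc = RasterScene(np.zeros((4, 4, 3), dtype=np.uint8), 0.5, origin=(10.0, 20.0))
        assert sc.pixel_to_map(0, 0) == (10.0, 20.0)
        assert sc.pixel_to_map(4, 4) == (12.0, 22.0)


class TestSegmentPolygon:
    def test_needs_three_distinct_vertices(self):
        with pytest.raises(GeometryError):
            SegmentPolygon.from_ring(1, [(0, 0), (1, 0), (1, 0)])

    def test_self_intersecting_ring_rejected_with_id(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(GeometryError, match="7"):
            SegmentPolygon.from_ring(7, bowtie)

    def test_holes_preserved_in_area(self):
        p = SegmentPolygon(
            1, Polygon([(0, 0), (4, 0), (4, 4), (0, 4)],
                       [[(1, 1), (1, 2), (2, 2), (2, 1)]])
        )
        assert p.area == pytest.approx(15.0)


class TestPolygonize:
    def test_full_grid_is_one_square(self):
        lm = LabelMap(np.ones((10, 10), dtype=np.int32))
        segs = polygonize(lm, scene_of(10, 10, 0.5))
        assert len(segs) == 1
        assert segs[0].area == pytest.approx(25.0)

    def test_two_blobs_give_two_polygons(self):
        lab = np.zeros((6, 6), dtype=np.int32)
        lab[:2, :2] = 1
        lab[4:, 4:] = 2
        segs = polygonize(LabelMap(lab), scene_of(6, 6))
        assert len(segs) == 2

    def test_l_shape_area_and_perimeter(self):
        # 3 pixels in an L at 1 m/pixel: area 3, boundary 8 edges
        lab = np.zeros((3, 3), dtype=np.int32)
        lab[0, 0] = lab[1, 0] = lab[1, 1] = 1
        segs = polygonize(LabelMap(lab), scene_of(3, 3))
        assert segs[0].area == pytest.approx(3.0)
        assert segs[0].perimeter == pytest.approx(8.0)

    def test_area_preserving_for_every_label(self):
        rng = np.random.default_rng(5)
        lab = rng.integers(1, 4, size=(12, 12)).astype(np.int32)
        # make each label 4-connected by taking one connected patch per label
        lab = np.zeros((12, 12), dtype=np.int32)
        lab[:5, :7] = 1
        lab[5:, :3] = 2
        lab[5:, 3:] = 3
        lab[:5, 7:] = 4
        sc = scene_of(12, 12, 0.25)
        segs = polygonize(LabelMap(lab), sc)
        for seg in segs:
            count = int((lab == seg.id).sum())
            assert seg.area == pytest.approx(count * 0.25**2)

    def test_misaligned_grid_raises(self):
        with pytest.raises(DimensionError):
            polygonize(LabelMap(np.ones((4, 4), dtype=np.int32)), scene_of(5, 4))

    def test_disconnected_label_rejected(self):
        lab = np.zeros((5, 5), dtype=np.int32)
        lab[0, 0] = 1
        lab[4, 4] = 1
        with pytest.raises(GeometryError):
            polygonize(LabelMap(lab), scene_of(5, 5))

    def test_diagonal_pinch_is_kept_as_single_segment(self):
        # 4-connected U-shape with a diagonal self-touch stays one segment
        lab = np.array(
            [[1, 1, 1],
             [1, 0, 1],
             [1, 1, 0]], dtype=np.int32)
        lab[2, 2] = 0
        segs = polygonize(LabelMap(lab), scene_of(3, 3))
        assert len(segs) == 1
        assert segs[0].area == pytest.approx(7.0)

    def test_roundtrip_with_rasterize(self):
        sc = scene_of(20, 20, 0.5)
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[2:8, 3:9] = 1
        lab[12:18, 10:17] = 2
        segs = polygonize(LabelMap(lab), sc)
        back = rasterize(segs.segments, sc)
        assert np.array_equal(back.labels, lab)


class TestOverlap:
    def test_identical_unit_squares(self):
        assert overlap_area(square(1, 0, 0), square(2, 0, 0)) == pytest.approx(1.0)

    def test_disjoint_squares(self):
        assert overlap_area(square(1, 0, 0), square(2, 5, 5)) == 0.0

    def test_half_overlapping_squares(self):
        assert overlap_area(square(1, 0, 0), square(2, 0.5, 0)) == pytest.approx(0.5)

    def test_symmetric_and_bounded_against_pixel_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            x1, y1, x2, y2 = rng.uniform(0, 4, size=4)
            w1, h1, w2, h2 = rng.uniform(0.5, 3, size=4)
            a = SegmentPolygon(1, box(x1, y1, x1 + w1, y1 + h1))
            b = SegmentPolygon(2, box(x2, y2, x2 + w2, y2 + h2))
            ov = overlap_area(a, b)
            assert ov == overlap_area(b, a)
            assert 0 <= ov <= min(a.area, b.area) + 1e-12
            assert ov == pytest.approx(pixel_overlap_area(a.geometry, b.geometry),
                                       abs=0.05)
            # complement identity: |a \ b| + |a ∩ b| = |a|
            assert a.geometry.difference(b.geometry).area + ov == pytest.approx(a.area)


class TestOutsideArea:
    def test_segment_inside_reference_is_zero(self):
        refs = ref_set(square(1, 0, 0, 4))
        assert outside_area(square(1, 1, 1), refs) == 0.0

    def test_disjoint_segment_is_own_area(self):
        refs = ref_set(square(1, 10, 10))
        seg = square(2, 0, 0, 2)
        assert outside_area(seg, refs) == pytest.approx(4.0)

    def test_half_covering(self):
        refs = ref_set(square(1, 0.5, 0))
        assert outside_area(square(9, 0, 0), refs) == pytest.approx(0.5)

    def test_monotone_in_reference_set(self):
        seg = square(1, 0, 0, 3)
        small = ref_set(square(1, 0, 0))
        bigger = ref_set(square(1, 0, 0), square(2, 1.5, 1.5))
        assert outside_area(seg, bigger) <= outside_area(seg, small)


def test_reference_set_disjointness_validation():
    refs = ref_set(square(1, 0, 0), square(2, 0.5, 0.5))
    with pytest.raises(GeometryError):
        refs.validate_disjoint()
    ref_set(square(1, 0, 0), square(2, 2, 2)).validate_disjoint()


def test_random_label_maps_polygonize_consistently():
    # partition property: labelled area equals summed polygon area
    rng = np.random.default_rng(11)
    sc = random_scene(rng, 9, 9)
    from scrubseg.mrs import MRSParams, segment

    lm = segment(sc, MRSParams(scale=60, shape=0.3, compactness=0.5))
    segs = polygonize(lm, sc)
    assert sum(s.area for s in segs) == pytest.approx(81.0)
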