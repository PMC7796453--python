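import pytest
from shapely import affinity
from shapely.geometry import box

from scrubseg.errors import MetricError
from scrubseg.geometry import ReferenceSet, SegmentPolygon, SegmentationSet
from scrubseg.metrics import (
    build_correspondence,
    compute_ed2,
    compute_nsr,
    compute_pse,
    evaluate,
    match_detections,
    prf,
    round_half_up,
)

from conftest import ref_set, seg_set, square


class TestCorrespondence:
    def test_identical_sets_fully_correspond(self):
        refs = ref_set(square(1, 0, 0, 2), square(2, 5, 5, 2))
        segs = seg_set(square(1, 0, 0, 2), square(2, 5, 5, 2))
        table = build_correspondence(segs, refs)
        assert table.v == table.m == 2
        assert {(s, r) for s, r, _ in table.pairs} == {(1, 1), (2, 2)}
        assert all(ov == pytest.approx(4.0) for _, _, ov in table.pairs)

    def test_disjoint_sets_empty_table(self):
        refs = ref_set(square(1, 0, 0))
        segs = seg_set(square(1, 10, 10))
        table = build_correspondence(segs, refs)
        assert table.pairs == [] and table.v == 0

    def test_straddling_segment_counts_once(self):
        # 3 segments over 2 references, one segment straddles both
        refs = ref_set(square(1, 0, 0, 2), square(2, 3, 0, 2))
        segs = seg_set(
            square(1, 0, 0, 2),                       # matches ref 1
            SegmentPolygon(2, box(1.5, 0.5, 3.5, 1.5)),  # straddles both
            square(3, 3, 0, 2),                       # matches ref 2
        )
        table = build_correspondence(segs, refs)
        assert table.v == 3
        assert len(table.pairs) == 4

    def test_grazing_background_segment_excluded(self):
        # a huge segment overlapping a tiny fraction of its area is not v
        refs = ref_set(square(1, 0, 0))
        segs = seg_set(SegmentPolygon(1, box(-50, -50, 50, 50)))
        assert build_correspondence(segs, refs).v == 0

    def test_empty_references_rejected(self):
        with pytest.raises(MetricError):
            build_correspondence(seg_set(square(1, 0, 0)), ReferenceSet([]))


class TestPSE:
    def test_perfect_segmentation_is_zero(self):
        refs = ref_set(square(1, 0, 0, 2))
        segs = seg_set(square(1, 0, 0, 2))
        table = build_correspondence(segs, refs)
        assert compute_pse(table, segs, refs) == 0.0

    def test_overestimation_ratio(self):
        # 2 m2 segment, 0.5 m2 outside; references total 2 m2 -> PSE 0.25
        refs = ref_set(
            SegmentPolygon(1, box(0, 0, 1, 1)),
            SegmentPolygon(2, box(5, 5, 6, 6)),
        )
        segs = seg_set(SegmentPolygon(1, box(0, 0, 1.5, 1)),
                       SegmentPolygon(2, box(5, 5, 6, 6)))
        table = build_correspondence(segs, refs)
        assert compute_pse(table, segs, refs) == pytest.approx(0.5 / 2.0)

    def test_disjoint_segments_do_not_contribute(self):
        refs = ref_set(square(1, 0, 0, 2))
        base = seg_set(square(1, 0, 0, 2))
        with_fp = seg_set(square(1, 0, 0, 2), square(2, 20, 20, 3))
        t1 = build_correspondence(base, refs)
        t2 = build_correspondence(with_fp, refs)
        assert compute_pse(t1, base, refs) == compute_pse(t2, with_fp, refs)


class TestNSRandED2:
    def test_nsr_values(self):
        assert compute_nsr(10, 10) == 0.0
        assert compute_nsr(10, 8) == pytest.approx(0.2)
        assert round_half_up(compute_nsr(62, 58), 4) == pytest.approx(0.0645)
        with pytest.raises(MetricError):
            compute_nsr(0, 3)

    def test_ed2_is_euclidean(self):
        assert compute_ed2(0, 0) == 0.0
        assert compute_ed2(0.03, 0.04) == pytest.approx(0.05)

    def test_ed2_reproduces_published_rows(self, segmentation_benchmark):
        for row in segmentation_benchmark:
            got = round_half_up(compute_ed2(row["pse"], row["nsr"]), 4)
            assert got == pytest.approx(row["ed2"], abs=1.0001e-4), row


class TestDetectionMatching:
    def test_identical_sets_all_tp(self):
        refs = ref_set(square(1, 0, 0, 2), square(2, 5, 0, 2))
        segs = seg_set(square(1, 0, 0, 2), square(2, 5, 0, 2))
        assert match_detections(segs, refs) == (2, 0, 0)

    def test_empty_predictions(self):
        refs = ref_set(square(1, 0, 0), square(2, 3, 3))
        assert match_detections(SegmentationSet([]), refs) == (0, 0, 2)

    def test_greedy_one_to_one(self):
        # two predictions over one reference: best IoU wins, other is FP
        refs = ref_set(SegmentPolygon(1, box(0, 0, 10, 10)))
        segs = seg_set(
            SegmentPolygon(1, box(0, 0, 10, 6)),   # IoU 0.6
            SegmentPolygon(2, box(0, 4.5, 10, 10)),  # IoU 0.55
        )
        assert match_detections(segs, refs, iou_threshold=0.5) == (1, 1, 0)

    def test_counts_partition(self):
        refs = ref_set(square(1, 0, 0, 2), square(2, 5, 5, 2), square(3, 9, 0, 2))
        segs = seg_set(square(1, 0.2, 0, 2), square(2, 30, 30))
        tp, fp, fn = match_detections(segs, refs)
        assert tp + fn == refs.m
        assert tp + fp == len(segs)


class TestPRF:
    def test_published_detection_rows_consistent_subset(self, detection_benchmark):
        # all rows whose printed scores are arithmetically self-consistent
        for row in detection_benchmark:
            if row["inconsistent"]:
                continue
            p, r, f1 = prf(row["tp"], row["fp"], row["fn"])
            assert round_half_up(p, 2) == pytest.approx(row["precision"]), row
            assert round_half_up(r, 2) == pytest.approx(row["recall"]), row
            assert round_half_up(f1, 2) == pytest.approx(row["f1"]), row

    def test_degenerate_conventions(self):
        assert prf(0, 0, 5) == (0.0, 0.0, 0.0)
        with pytest.raises(MetricError):
            prf(0, 0, 0)
        with pytest.raises(MetricError):
            prf(-1, 0, 1)


class TestInvariances:
    def build_pair(self):
        refs = ref_set(square(1, 0, 0, 4), square(2, 10, 2, 3))
        segs = seg_set(
            SegmentPolygon(1, box(-0.5, 0, 4, 4.2)),
            SegmentPolygon(2, box(10.5, 2, 13.2, 5)),
            square(3, 30, 30),
        )
        return segs, refs

    @pytest.mark.parametrize("factor,shift", [(3.7, (0, 0)), (1.0, (120, -45)),
                                              (0.25, (7, 7))])
    def test_similarity_transform_invariance(self, factor, shift):
        segs, refs = self.build_pair()
        base = evaluate(segs, refs)

        def xf(p):
            g = affinity.scale(p.geometry, xfact=factor, yfact=factor,
                               origin=(0, 0))
            return SegmentPolygon(p.id, affinity.translate(g, *shift))

        segs2 = SegmentationSet([xf(s) for s in segs])
        refs2 = ReferenceSet([xf(r) for r in refs])
        other = evaluate(segs2, refs2)
        for fieldname in ("pse", "nsr", "ed2", "precision", "recall", "f1"):
            assert getattr(other, fieldname) == pytest.approx(
                getattr(base, fieldname)), fieldname
        assert (other.tp, other.fp, other.fn) == (base.tp, base.fp, base.fn)

    def test_identity_evaluation_is_perfect(self):
        refs = ref_set(square(1, 0, 0, 2), square(2, 4, 4, 3))
        segs = seg_set(square(1, 0, 0, 2), square(2, 4, 4, 3))
        rep = evaluate(segs, refs)
        assert (rep.pse, rep.nsr, rep.ed2) == (0.0, 0.0, 0.0)
        assert (rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0)
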