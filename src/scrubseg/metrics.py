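"""Segmentation accuracy assessment.

Two complementary views of agreement with expert-digitised reference
polygons:

* geometric/arithmetic discrepancy of the segmentation itself —
  PSE (potential segmentation error), NSR (number-of-segmentation ratio)
  and their Euclidean combination ED2:

      PSE = sum_i outside(s_i) / sum_k area(r_k)      over corresponding s_i
      NSR = |m - v| / m
      ED2 = sqrt(PSE^2 + NSR^2)

  where m is the reference count and v the number of *corresponding*
  segments.  A segment corresponds to the reference set when its overlap
  with the reference union exceeds max(sliver, 5% of its own area); the 5%
  cut keeps large background segments that merely graze a shrub out of v
  and out of PSE.

* object-level detection quality — one-to-one matching of predicted
  segments to references by descending IoU (intersection over union, default
  threshold 0.5), yielding TP/FP/FN and Precision/Recall/F1.

ED2 = 0 means perfect geometric and arithmetic agreement; both families are
invariant under uniform scaling and translation of all coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from shapely.strtree import STRtree

from .errors import MetricError
from .geometry import (
    SLIVER_AREA,
    ReferenceSet,
    SegmentationSet,
    outside_area,
)

#: A segment corresponds to the references when its overlap with the
#: reference union exceeds this fraction of its own area.
CORRESPONDENCE_FRACTION = 0.05

#: Default IoU threshold for counting a detection as a true positive.
IOU_THRESHOLD = 0.5


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up at ``ndigits``, as printed result tables use."""
    q = Decimal("1." + "0" * ndigits) if ndigits else Decimal("1")
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CorrespondenceTable:
    """Segment-reference overlap bookkeeping.

    ``pairs`` holds (segment id, reference id, overlap m^2) for every
    positive overlap; ``corresponding_ids`` the segments passing the
    correspondence rule; ``v`` and ``m`` feed NSR.
    """

    pairs: list[tuple[int, int, float]]
    corresponding_ids: list[int]
    m: int

    @property
    def v(self) -> int:
        return len(self.corresponding_ids)


@dataclass
class AccuracyReport:
    """PSE/NSR/ED2 plus detection counts and scores for one segmentation."""

    pse: float
    nsr: float
    ed2: float
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    m: int = 0
    v: int = 0
    provenance: dict = field(default_factory=dict)


def build_correspondence(
    segs: SegmentationSet,
    refs: ReferenceSet,
    correspondence_threshold: float = CORRESPONDENCE_FRACTION,
) -> CorrespondenceTable:
    """Overlap table between segments and references.

    Deterministic: segments are visited in id order, reference pairs stored
    in (segment id, reference id) order.
    """
    if refs.m == 0:
        raise MetricError("reference set is empty")
    ref_geoms = [r.geometry for r in refs]
    tree = STRtree(ref_geoms)
    union = refs.union()
    pairs: list[tuple[int, int, float]] = []
    corresponding: list[int] = []
    for seg in sorted(segs, key=lambda s: s.id):
        candidates = sorted(tree.query(seg.geometry).tolist())
        for idx in candidates:
            ov = seg.geometry.intersection(ref_geoms[idx]).area
            if ov > SLIVER_AREA:
                pairs.append((seg.id, refs.polygons[idx].id, ov))
        total_ov = seg.geometry.intersection(union).area
        if total_ov > max(SLIVER_AREA, correspondence_threshold * seg.area):
            corresponding.append(seg.id)
    return CorrespondenceTable(pairs=pairs, corresponding_ids=corresponding, m=refs.m)


def compute_pse(
    table: CorrespondenceTable, segs: SegmentationSet, refs: ReferenceSet
) -> float:
    """Potential segmentation error: overestimated area over reference area.

    Only corresponding segments contribute; disjoint (non-corresponding)
    segments are a detection problem, not a geometric one.
    """
    total_ref = refs.total_area
    if refs.m == 0 or total_ref <= 0:
        raise MetricError("PSE undefined: empty reference set")
    over = 0.0
    wanted = set(table.corresponding_ids)
    for seg in segs:
        if seg.id in wanted:
            over += outside_area(seg, refs)
    return over / total_ref


def compute_nsr(m: int, v: int) -> float:
    """Number-of-segmentation ratio |m - v| / m."""
    if m < 1:
        raise MetricError("NSR undefined: m must be >= 1")
    return abs(m - v) / m


def compute_ed2(pse: float, nsr: float) -> float:
    """Euclidean combination sqrt(PSE^2 + NSR^2)."""
    if pse < 0 or nsr < 0:
        raise MetricError("PSE and NSR must be non-negative")
    return float((pse * pse + nsr * nsr) ** 0.5)


def _iou(a, b) -> float:
    inter = a.intersection(b).area
    if inter <= 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def match_detections(
    segs: SegmentationSet,
    refs: ReferenceSet,
    iou_threshold: float = IOU_THRESHOLD,
) -> tuple[int, int, int]:
    """Greedy one-to-one detection matching by descending IoU.

    Returns (TP, FP, FN) with TP + FN = m and TP + FP = number of predicted
    segments.  Ties in IoU break on (segment id, reference id).
    """
    if not (0 < iou_threshold <= 1):
        raise MetricError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    ref_geoms = [r.geometry for r in refs]
    tree = STRtree(ref_geoms) if ref_geoms else None
    candidates: list[tuple[float, int, int]] = []
    for seg in segs:
        if tree is None:
            break
        for idx in sorted(tree.query(seg.geometry).tolist()):
            iou = _iou(seg.geometry, ref_geoms[idx])
            if iou >= iou_threshold:
                candidates.append((iou, seg.id, refs.polygons[idx].id))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_segs: set[int] = set()
    used_refs: set[int] = set()
    tp = 0
    for _, sid, rid in candidates:
        if sid in used_segs or rid in used_refs:
            continue
        used_segs.add(sid)
        used_refs.add(rid)
        tp += 1
    fp = len(segs) - tp
    fn = refs.m - tp
    return tp, fp, fn


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from detection counts.

    Degenerate denominators follow the usual conventions: precision (recall)
    is 0 when it has no denominator, and F1 is 0 when P + R = 0.
    """
    if min(tp, fp, fn) < 0:
        raise MetricError("counts must be non-negative")
    if tp + fp + fn == 0:
        raise MetricError("P/R/F1 undefined: all counts are zero")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def evaluate(
    segs: SegmentationSet,
    refs: ReferenceSet,
    iou_threshold: float = IOU_THRESHOLD,
    correspondence_threshold: float = CORRESPONDENCE_FRACTION,
) -> AccuracyReport:
    """Full accuracy report of one segmentation against the references."""
    table = build_correspondence(segs, refs, correspondence_threshold)
    pse = compute_pse(table, segs, refs)
    nsr = compute_nsr(table.m, table.v)
    ed2 = compute_ed2(pse, nsr)
    tp, fp, fn = match_detections(segs, refs, iou_threshold)
    precision, recall, f1 = prf(tp, fp, fn)
    return AccuracyReport(
        pse=pse,
        nsr=nsr,
        ed2=ed2,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        m=table.m,
        v=table.v,
        provenance=dict(segs.provenance),
    )
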