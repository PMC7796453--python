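"""Consensus fusion of two independent segmentations.

Two segmentations of the same scene — e.g. a region-merging (OBIA) result O
and an instance-segmentation (CNN) result C — are fused by intersecting
matched segment pairs:

    OC_ij = o_i  intersect  c_j

The intersection can only shrink a segment, so area lying outside the
reference shrubs (the overestimation that drives PSE) never grows; when the
two inputs carry independent error modes (one dilates, the other shifts),
the consensus is typically more accurate than either input.

Pairing is one-to-one by descending overlap area with deterministic id
tie-breaks.  Segments left unmatched (when the two inputs disagree on the
object count) are excluded from the consensus but reported in the
side-channel fields of :class:`FusedSegmentation` for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry import MultiPolygon, Polygon
from shapely.strtree import STRtree

from .errors import FusionError, GeometryError
from .geometry import SLIVER_AREA, SegmentPolygon, SegmentationSet


@dataclass
class PairAssignment:
    """One-to-one matched segment pairs and the leftovers of each side."""

    pairs: list[tuple[int, int, float]]  # (o_id, c_id, overlap m^2)
    unmatched_o: list[int]
    unmatched_c: list[int]


@dataclass
class FusedSegmentation:
    """Consensus polygons plus the pairing that produced them.

    ``parents`` maps each fused segment id to its (o_id, c_id) pair.
    """

    segments: SegmentationSet
    assignment: PairAssignment
    parents: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def pair_segments(o: SegmentationSet, c: SegmentationSet) -> PairAssignment:
    """Match segments across two sets, greedily by descending overlap.

    Raises :class:`FusionError` when either side is empty.  Ties in overlap
    break on (o id, c id); only positive (non-sliver) overlaps can pair.
    """
    if len(o) == 0 or len(c) == 0:
        raise FusionError("cannot pair with an empty segmentation")
    c_geoms = [s.geometry for s in c]
    tree = STRtree(c_geoms)
    candidates: list[tuple[float, int, int]] = []
    for seg in o:
        for idx in sorted(tree.query(seg.geometry).tolist()):
            ov = seg.geometry.intersection(c_geoms[idx]).area
            if ov > SLIVER_AREA:
                candidates.append((ov, seg.id, c.segments[idx].id))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_o: set[int] = set()
    used_c: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for ov, oid, cid in candidates:
        if oid in used_o or cid in used_c:
            continue
        used_o.add(oid)
        used_c.add(cid)
        pairs.append((oid, cid, ov))
    pairs.sort(key=lambda t: (t[0], t[1]))
    return PairAssignment(
        pairs=pairs,
        unmatched_o=[s.id for s in o if s.id not in used_o],
        unmatched_c=[s.id for s in c if s.id not in used_c],
    )


def _largest_part(geom) -> Polygon | None:
    """Largest polygonal part of an intersection result, or None if empty."""
    if isinstance(geom, Polygon):
        return None if geom.is_empty else geom
    parts: list[Polygon] = []
    if isinstance(geom, MultiPolygon):
        parts = list(geom.geoms)
    elif hasattr(geom, "geoms"):  # GeometryCollection
        parts = [g for g in geom.geoms if isinstance(g, Polygon)]
    if not parts:
        return None
    return max(parts, key=lambda g: g.area)


def fuse(o: SegmentationSet, c: SegmentationSet) -> FusedSegmentation:
    """Intersect matched pairs into a consensus segmentation.

    One consensus polygon per matched pair: where the raw intersection breaks
    into several parts, the largest is kept (one object per shrub pair);
    parts below the sliver tolerance are dropped.  Commutative and, up to the
    sliver filter, idempotent (``fuse(X, X)`` reproduces X).
    """
    assignment = pair_segments(o, c)
    fused: list[SegmentPolygon] = []
    parents: dict[int, tuple[int, int]] = {}
    next_id = 1
    for oid, cid, _ in assignment.pairs:
        try:
            inter = o.get(oid).geometry.intersection(c.get(cid).geometry)
        except Exception as exc:  # pragma: no cover - shapely internal failure
            raise GeometryError(f"intersection failed for pair ({oid}, {cid}): {exc}")
        part = _largest_part(inter)
        if part is None or part.area < SLIVER_AREA:
            continue
        fused.append(SegmentPolygon(next_id, part))
        parents[next_id] = (oid, cid)
        next_id += 1
    provenance = {
        "method": "fusion",
        "inputs": [dict(o.provenance), dict(c.provenance)],
    }
    return FusedSegmentation(
        segments=SegmentationSet(fused, provenance),
        assignment=assignment,
        parents=parents,
    )
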