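"""Core domain types and geometric primitives.

The toolkit works in map coordinates (metres).  The convention throughout is
the one used by image-derived geodata: the map origin sits at the top-left
corner of the top-left pixel, x grows with the pixel column and y grows with
the pixel row (i.e. downwards in image space).  Pixel (row, col) covers the
half-open square [col*res, (col+1)*res) x [row*res, (row+1)*res) offset by the
scene origin, so polygon vertices produced from rasters lie on pixel corners
and pixel areas are exactly ``resolution**2``.

Shapely backs all polygon arithmetic; the classes here only add identity,
validation and unit bookkeeping on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.geometry.polygon import orient
from shapely.ops import unary_union

from .errors import DataError, DimensionError, GeometryError

#: Areas/overlaps below this (m^2) are floating-point slivers, treated as zero.
SLIVER_AREA = 1e-6


# ---------------------------------------------------------------------------
# raster side
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RasterScene:
    """An RGB pixel grid with ground resolution and a map-space anchor.

    Parameters
    ----------
    pixels:
        ``(rows, cols, 3)`` integer array with values in [0, 255].
    resolution:
        Ground sampling distance in metres per pixel (square pixels).
    origin:
        Map coordinate ``(x, y)`` of the top-left corner of pixel (0, 0).
    """

    pixels: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise DimensionError(
                f"pixels must be (rows, cols, 3), got shape {px.shape}"
            )
        if not np.issubdtype(px.dtype, np.integer):
            if not np.isfinite(px).all():
                raise DataError("pixel data contains non-finite values")
        if px.min() < 0 or px.max() > 255:
            raise DataError("pixel values must lie in [0, 255]")
        if not (self.resolution > 0):
            raise DataError(f"resolution must be > 0, got {self.resolution}")
        object.__setattr__(self, "pixels", px)

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def plot_extent(self) -> tuple[float, float]:
        """(width, height) of the scene footprint in metres."""
        return (self.cols * self.resolution, self.rows * self.resolution)

    def pixel_to_map(self, col: float, row: float) -> tuple[float, float]:
        """Map coordinate of a pixel-grid position (corner convention)."""
        ox, oy = self.origin
        return (ox + col * self.resolution, oy + row * self.resolution)


@dataclass(frozen=True)
class LabelMap:
    """Integer region labels aligned to a :class:`RasterScene`.

    Label 0 is background; every positive label is expected to cover one
    4-connected pixel region.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise DimensionError(f"labels must be 2-D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise DataError("labels must be integers")
        if lab.min() < 0:
            raise DataError("labels must be non-negative")
        object.__setattr__(self, "labels", lab)

    @property
    def ids(self) -> np.ndarray:
        """Sorted non-background labels present in the map."""
        u = np.unique(self.labels)
        return u[u > 0]

    def validate_connectivity(self) -> None:
        """Raise if any label covers more than one 4-connected region."""
        struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for lab in self.ids:
            _, n = ndimage.label(self.labels == lab, structure=struct)
            if n != 1:
                raise GeometryError(f"label {lab} covers {n} disjoint regions")


# ---------------------------------------------------------------------------
# vector side
# ---------------------------------------------------------------------------


def _as_valid_polygon(geometry, pid: object):
    """Validate a segment geometry.

    Normally a Polygon; a MultiPolygon is tolerated for the edge case of a
    4-connected pixel region pinched at a diagonal corner, which GEOS can
    only represent as point-touching parts.
    """
    if isinstance(geometry, Polygon):
        if geometry.is_empty or len(geometry.exterior.coords) < 4:
            raise GeometryError(
                f"segment {pid}: ring needs at least 3 distinct vertices"
            )
    elif not isinstance(geometry, MultiPolygon):
        raise GeometryError(
            f"segment {pid}: expected a polygon, got {geometry.geom_type}"
        )
    if not geometry.is_valid:
        raise GeometryError(f"segment {pid}: invalid ring (self-intersection?)")
    if geometry.area <= 0:
        raise GeometryError(f"segment {pid}: non-positive area")
    return geometry


@dataclass(frozen=True)
class SegmentPolygon:
    """A single segment: integer id plus a valid shapely polygon in metres."""

    id: int
    geometry: Polygon

    def __post_init__(self) -> None:
        _as_valid_polygon(self.geometry, self.id)

    @classmethod
    def from_ring(
        cls,
        pid: int,
        ring: Sequence[tuple[float, float]],
        holes: Sequence[Sequence[tuple[float, float]]] | None = None,
    ) -> "SegmentPolygon":
        return cls(pid, Polygon(ring, holes or []))

    @property
    def area(self) -> float:
        """Area in m^2."""
        return self.geometry.area

    @property
    def perimeter(self) -> float:
        """Outer + inner boundary length in metres."""
        return self.geometry.length


@dataclass
class SegmentationSet:
    """A collection of candidate segments with provenance.

    ``provenance`` records where the segmentation came from (method name and
    its parameters) so that reports and fused outputs stay traceable.
    """

    segments: list[SegmentPolygon]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(ids) != len(set(ids)):
            raise GeometryError("segment ids must be unique")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[SegmentPolygon]:
        return iter(self.segments)

    def __getitem__(self, i: int) -> SegmentPolygon:
        return self.segments[i]

    @property
    def total_area(self) -> float:
        return sum(s.area for s in self.segments)

    def get(self, pid: int) -> SegmentPolygon:
        for s in self.segments:
            if s.id == pid:
                return s
        raise KeyError(pid)

    @classmethod
    def from_geometries(
        cls, geometries: Iterable[Polygon], provenance: dict | None = None
    ) -> "SegmentationSet":
        segs = [SegmentPolygon(i + 1, g) for i, g in enumerate(geometries)]
        return cls(segs, provenance or {})


@dataclass
class ReferenceSet:
    """Expert ground-truth polygons r_k; ``m`` is their count.

    Reference shrub outlines must be pairwise disjoint (interiors); touching
    boundaries are tolerated.
    """

    polygons: list[SegmentPolygon]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.polygons]
        if len(ids) != len(set(ids)):
            raise GeometryError("reference ids must be unique")
        self._union = None

    @property
    def m(self) -> int:
        return len(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)

    def __iter__(self) -> Iterator[SegmentPolygon]:
        return iter(self.polygons)

    @property
    def total_area(self) -> float:
        return sum(p.area for p in self.polygons)

    @property
    def mean_area(self) -> float:
        return self.total_area / self.m if self.m else 0.0

    def union(self):
        """Cached union of all reference geometries."""
        if self._union is None:
            self._union = unary_union([p.geometry for p in self.polygons])
        return self._union

    def validate_disjoint(self, tolerance: float = SLIVER_AREA) -> None:
        polys = self.polygons
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                inter = polys[i].geometry.intersection(polys[j].geometry)
                if inter.area > tolerance:
                    raise GeometryError(
                        f"reference polygons {polys[i].id} and {polys[j].id} overlap"
                    )

    @classmethod
    def from_geometries(cls, geometries: Iterable[Polygon]) -> "ReferenceSet":
        return cls([SegmentPolygon(i + 1, g) for i, g in enumerate(geometries)])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _label_runs(row_labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal same-label runs of one label row as (label, col_start, col_stop)."""
    out = []
    n = row_labels.size
    start = 0
    for c in range(1, n + 1):
        if c == n or row_labels[c] != row_labels[start]:
            out.append((int(row_labels[start]), start, c))
            start = c
    return out


def polygonize(label_map: LabelMap, scene: RasterScene) -> SegmentationSet:
    """Convert a label map into one map-unit polygon per label.

    Each pixel contributes its exact ``resolution**2`` square, so the polygon
    area of a label equals its pixel count times the pixel area (holes are
    preserved, not filled).  Labels must be 4-connected single regions.
    """
    lab = label_map.labels
    if lab.shape != (scene.rows, scene.cols):
        raise DimensionError(
            f"label map shape {lab.shape} does not match scene "
            f"({scene.rows}, {scene.cols})"
        )
    res = scene.resolution
    ox, oy = scene.origin

    boxes: dict[int, list] = {}
    for r in range(lab.shape[0]):
        y0 = oy + r * res
        y1 = y0 + res
        for label, c0, c1 in _label_runs(lab[r]):
            if label == 0:
                continue
            boxes.setdefault(label, []).append(
                box(ox + c0 * res, y0, ox + c1 * res, y1)
            )

    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    segments = []
    for label in sorted(boxes):
        geom = unary_union(boxes[label])
        if isinstance(geom, MultiPolygon):
            # GEOS splits regions pinched at a diagonal corner into
            # point-touching parts; accept those, reject true disconnection.
            _, n_parts = ndimage.label(lab == label, structure=struct)
            if n_parts != 1:
                raise GeometryError(f"label {label} covers disjoint regions")
        segments.append(SegmentPolygon(int(label), geom))
    return SegmentationSet(segments, provenance={"method": "polygonize"})


def rasterize(
    polygons: Iterable[SegmentPolygon],
    scene: RasterScene,
) -> LabelMap:
    """Burn polygons into a label grid by the pixel-centre (majority) rule.

    Later polygons overwrite earlier ones where they overlap; background is 0.
    """
    import shapely

    res = scene.resolution
    ox, oy = scene.origin
    lab = np.zeros((scene.rows, scene.cols), dtype=np.int32)
    for poly in polygons:
        minx, miny, maxx, maxy = poly.geometry.bounds
        c0 = max(0, int(np.floor((minx - ox) / res)))
        c1 = min(scene.cols, int(np.ceil((maxx - ox) / res)))
        r0 = max(0, int(np.floor((miny - oy) / res)))
        r1 = min(scene.rows, int(np.ceil((maxy - oy) / res)))
        if c1 <= c0 or r1 <= r0:
            continue
        cols = ox + (np.arange(c0, c1) + 0.5) * res
        rows = oy + (np.arange(r0, r1) + 0.5) * res
        xx, yy = np.meshgrid(cols, rows)
        inside = shapely.contains_xy(poly.geometry, xx.ravel(), yy.ravel())
        window = lab[r0:r1, c0:c1]
        window[inside.reshape(window.shape)] = poly.id
    return LabelMap(lab)


def overlap_area(a: SegmentPolygon, b: SegmentPolygon) -> float:
    """Intersection area of two segments in m^2 (symmetric, sliver-filtered)."""
    ga = _as_valid_polygon(a.geometry, a.id)
    gb = _as_valid_polygon(b.geometry, b.id)
    area = ga.intersection(gb).area
    return 0.0 if area < SLIVER_AREA else area


def outside_area(seg: SegmentPolygon, refs: ReferenceSet) -> float:
    """Area of ``seg`` falling outside the union of all reference polygons.

    This is the per-segment overestimation term feeding the potential
    segmentation error: area(seg) - area(seg intersected with union(refs)).
    """
    g = _as_valid_polygon(seg.geometry, seg.id)
    if refs.m == 0:
        return g.area
    out = g.area - g.intersection(refs.union()).area
    if out < SLIVER_AREA:
        return 0.0
    return min(out, g.area)


def normalized(polygon):
    """Counter-clockwise outer rings, clockwise holes (GeoJSON orientation)."""
    if isinstance(polygon, MultiPolygon):
        return MultiPolygon([orient(p, sign=1.0) for p in polygon.geoms])
    return orient(polygon, sign=1.0)
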