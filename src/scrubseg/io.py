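"""Readers and writers for the formats the toolkit touches.

Vector data travels as GeoJSON (RFC 7946) with counter-clockwise outer
rings; training-annotation polygons are read from VGG Image Annotator JSON
exports (both the 1.x list-valued and 2.x dict-valued ``regions`` dialects).
Rasters are plain TIFF or PNG accompanied by a small JSON sidecar
(``<file>.aux.json``) holding the ground resolution and the map coordinate
of the top-left pixel corner — the world metadata a GeoTIFF would carry.
Accuracy reports round-trip as JSON (full precision) or CSV (fixed decimal
formatting: 4 places for PSE/NSR/ED2, 2 for precision/recall/F1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon, mapping, shape

from .errors import BoundsError, FormatError
from .geometry import (
    RasterScene,
    ReferenceSet,
    SegmentPolygon,
    SegmentationSet,
    normalized,
)
from .metrics import AccuracyReport, round_half_up

# ---------------------------------------------------------------------------
# VGG Image Annotator JSON
# ---------------------------------------------------------------------------


@dataclass
class ImageAnnotation:
    """Polygon regions of one annotated image, in pixel coordinates."""

    filename: str
    regions: list[tuple[list[float], list[float]]]  # (all_points_x, all_points_y)


@dataclass
class AnnotationDocument:
    """A VGG Image Annotator export: named images with polygon regions."""

    images: list[ImageAnnotation]

    @property
    def n_regions(self) -> int:
        return sum(len(img.regions) for img in self.images)


def read_vgg_json(path: str | Path) -> AnnotationDocument:
    """Parse a VGG Image Annotator polygon export.

    Accepts both dialects found in the wild: ``regions`` as a list (VIA 2.x)
    or as a dict keyed by region index (VIA 1.x).  Raises
    :class:`FormatError` naming the first offending record.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})")
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: expected a top-level object keyed by image")
    # VIA projects sometimes nest the image map under _via_img_metadata
    if "_via_img_metadata" in doc:
        doc = doc["_via_img_metadata"]
    images = []
    for key, record in doc.items():
        if not isinstance(record, dict) or "regions" not in record:
            raise FormatError(f"{path}: record {key!r} has no 'regions' field")
        raw = record["regions"]
        if isinstance(raw, dict):
            raw = [raw[k] for k in sorted(raw, key=str)]
        elif not isinstance(raw, list):
            raise FormatError(f"{path}: record {key!r}: 'regions' must be list or dict")
        regions = []
        for i, region in enumerate(raw):
            try:
                sa = region["shape_attributes"]
                xs = [float(v) for v in sa["all_points_x"]]
                ys = [float(v) for v in sa["all_points_y"]]
            except (KeyError, TypeError) as exc:
                raise FormatError(
                    f"{path}: record {key!r} region {i}: missing {exc}"
                )
            if len(xs) != len(ys) or len(xs) < 3:
                raise FormatError(
                    f"{path}: record {key!r} region {i}: need >= 3 paired vertices"
                )
            regions.append((xs, ys))
        images.append(
            ImageAnnotation(filename=str(record.get("filename", key)), regions=regions)
        )
    return AnnotationDocument(images=images)


def annotations_to_segmentation(
    doc: AnnotationDocument, scene: RasterScene
) -> SegmentationSet:
    """Convert pixel-coordinate annotation polygons to map units.

    Vertices sit on the pixel grid (corner convention), so coordinates up to
    and including the image width/height are on the boundary and accepted;
    anything beyond raises :class:`BoundsError`.
    """
    geoms = []
    for img in doc.images:
        for i, (xs, ys) in enumerate(img.regions):
            for x, y in zip(xs, ys):
                if not (0 <= x <= scene.cols and 0 <= y <= scene.rows):
                    raise BoundsError(
                        f"{img.filename} region {i}: vertex ({x}, {y}) outside "
                        f"the {scene.cols} x {scene.rows} pixel grid"
                    )
            ring = [scene.pixel_to_map(x, y) for x, y in zip(xs, ys)]
            geoms.append(Polygon(ring))
    return SegmentationSet.from_geometries(
        geoms, provenance={"method": "annotations", "source": "vgg-json"}
    )


# ---------------------------------------------------------------------------
# GeoJSON polygon sets
# ---------------------------------------------------------------------------


def write_geojson(
    segs: SegmentationSet | ReferenceSet | Iterable[SegmentPolygon],
    path: str | Path,
) -> None:
    """Write a polygon set as a GeoJSON FeatureCollection (CCW outer rings)."""
    if isinstance(segs, SegmentationSet):
        polys: Sequence[SegmentPolygon] = segs.segments
        provenance = segs.provenance
    elif isinstance(segs, ReferenceSet):
        polys = segs.polygons
        provenance = {"method": "reference"}
    else:
        polys = list(segs)
        provenance = {}
    features = [
        {
            "type": "Feature",
            "properties": {"id": p.id},
            "geometry": mapping(normalized(p.geometry)),
        }
        for p in polys
    ]
    fc = {"type": "FeatureCollection", "features": features}
    if provenance:
        fc["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_geojson(path: str | Path) -> SegmentationSet:
    """Read a GeoJSON FeatureCollection of polygons into a SegmentationSet."""
    path = Path(path)
    with open(path) as fh:
        try:
            fc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})")
    if fc.get("type") != "FeatureCollection" or "features" not in fc:
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    segments = []
    for i, feature in enumerate(fc["features"]):
        geom = shape(feature.get("geometry") or {})
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise FormatError(
                f"{path}: feature {i} is {geom.geom_type}, expected Polygon"
            )
        pid = feature.get("properties", {}).get("id", i + 1)
        segments.append(SegmentPolygon(int(pid), normalized(geom)))
    return SegmentationSet(segments, provenance=fc.get("provenance", {}))


def read_reference_geojson(path: str | Path) -> ReferenceSet:
    segs = read_geojson(path)
    return ReferenceSet(segs.segments)


# ---------------------------------------------------------------------------
# rasters (TIFF/PNG + JSON sidecar georeferencing)
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".aux.json")


def write_raster(scene: RasterScene, path: str | Path) -> None:
    """Write scene pixels (TIFF or PNG by extension) plus the world sidecar."""
    path = Path(path)
    data = np.ascontiguousarray(scene.pixels.astype(np.uint8))
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)
    meta = {"resolution": scene.resolution, "origin": list(scene.origin)}
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh)


def read_raster(path: str | Path) -> RasterScene:
    """Read a raster written by :func:`write_raster` (requires the sidecar)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if not sidecar.exists():
        raise FormatError(f"{path}: missing world sidecar {sidecar.name}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    if data.ndim == 2:
        data = np.stack([data] * 3, axis=-1)
    if data.shape[2] > 3:
        data = data[:, :, :3]
    with open(sidecar) as fh:
        meta = json.load(fh)
    return RasterScene(
        data.astype(np.uint8), float(meta["resolution"]), tuple(meta["origin"])
    )


# ---------------------------------------------------------------------------
# accuracy reports
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("pse", "nsr", "ed2", "tp", "fp", "fn", "precision", "recall", "f1")


def _format_csv_value(column: str, value) -> str:
    if column in ("pse", "nsr", "ed2"):
        return f"{round_half_up(float(value), 4):.4f}"
    if column in ("precision", "recall", "f1"):
        return f"{round_half_up(float(value), 2):.2f}"
    return str(int(value))


def write_report(
    report: AccuracyReport | Sequence[AccuracyReport],
    path: str | Path,
    format: str = "json",
) -> None:
    """Write one or more accuracy reports.

    JSON keeps full floating precision (bit-exact round trip through
    :func:`read_report`); CSV uses the fixed table formatting (4 decimals for
    the ED2 family, 2 for detection scores).  An empty sequence yields a
    header-only CSV / an empty JSON list.
    """
    reports = [report] if isinstance(report, AccuracyReport) else list(report)
    for r in reports:
        for col in _CSV_COLUMNS:
            v = getattr(r, col)
            if not np.isfinite(v):
                raise FormatError(f"report field {col} is not finite: {v}")
    path = Path(path)
    if format == "json":
        payload = [dataclasses.asdict(r) for r in reports]
        if isinstance(report, AccuracyReport):
            payload = payload[0]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    elif format == "csv":
        lines = [",".join(_CSV_COLUMNS)]
        for r in reports:
            lines.append(
                ",".join(_format_csv_value(c, getattr(r, c)) for c in _CSV_COLUMNS)
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise FormatError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> AccuracyReport | list[AccuracyReport]:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        payload = json.load(fh)
    def _one(d: dict) -> AccuracyReport:
        return AccuracyReport(**d)
    if isinstance(payload, list):
        return [_one(d) for d in payload]
    return _one(payload)
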