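"""Synthetic scattered-shrub scenes with known ground truth.

The generator emulates the study system the toolkit targets: square dryland
plots (250 x 250 m by default) of scattered hemispherical shrub canopies —
irregular, roughly circular crowns between 12 and 311 m^2 — on a bare-soil
matrix, rendered as RGB rasters at sub-metre resolutions (0.5, 0.1 or
0.03 m/pixel).  Canopy outlines are random star-convex polygons whose radial
roughness exercises the shape terms of the merge criterion; colours are
per-class Gaussian noise around a dark-green shrub mean and a pale soil
mean.

Alongside the renderer there is a controlled perturbation model that turns a
reference set into an imperfect "candidate" segmentation with a known error
mode (dilation, erosion, shift, split, merge, dropped or spurious objects,
boundary smoothing).  Two independently perturbed copies stand in for the
region-merging and CNN outputs when exercising the fusion stage.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; child generators derive their seeds
deterministically, so every artefact is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from shapely import affinity
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import split as shapely_split
from shapely.ops import unary_union

from .errors import SpecError
from .geometry import (
    RasterScene,
    ReferenceSet,
    SegmentPolygon,
    SegmentationSet,
    rasterize,
)

PERTURB_MODES = (
    "dilate",
    "erode",
    "shift",
    "split",
    "merge",
    "drop",
    "spurious",
    "smooth-boundary",
)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scattered-shrub plot.

    Defaults mirror the target system: a 250 x 250 m plot holding 60 shrubs
    with canopy areas drawn uniformly from [12, 311] m^2, imaged at
    0.5 m/pixel.  ``roughness`` is the relative amplitude of the radial
    boundary noise (0 gives near-circles); ``min_gap`` the smallest allowed
    distance between canopies in metres.
    """

    plot_size: tuple[float, float] = (250.0, 250.0)
    resolution: float = 0.5
    n_shrubs: int = 60
    canopy_area_range: tuple[float, float] = (12.0, 311.0)
    roughness: float = 0.15
    n_vertices: int = 48
    shrub_color: tuple[float, float, float] = (60.0, 90.0, 50.0)
    soil_color: tuple[float, float, float] = (150.0, 130.0, 110.0)
    color_sigma: float = 10.0
    background_texture: float = 0.0
    min_gap: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.n_shrubs < 0:
            raise SpecError("resolution must be > 0 and n_shrubs >= 0")
        lo, hi = self.canopy_area_range
        if not (0 < lo <= hi):
            raise SpecError(f"invalid canopy area range {self.canopy_area_range}")
        if self.min_gap < 0 or self.roughness < 0:
            raise SpecError("min_gap and roughness must be non-negative")


@dataclass(frozen=True)
class PerturbSpec:
    """One error mode applied to a reference set.

    ``magnitude`` is in metres for the geometric modes (dilate, erode, shift,
    smooth-boundary, spurious object radius) and unused for the count modes
    (drop, split, merge), which are governed by ``probability`` — the
    per-object chance of applying the mode.
    """

    mode: str
    magnitude: float = 0.0
    probability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in PERTURB_MODES:
            raise SpecError(f"unknown perturbation mode {self.mode!r}")
        if self.magnitude < 0:
            raise SpecError("magnitude must be non-negative")
        if not (0 <= self.probability <= 1):
            raise SpecError("probability must be in [0, 1]")


def _star_polygon(
    rng: np.random.Generator,
    area: float,
    roughness: float,
    n_vertices: int,
) -> Polygon:
    """Random star-convex canopy outline of (almost exactly) the given area."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    radii = np.ones(n_vertices)
    # low-order radial harmonics; amplitude decays with harmonic order
    for h in range(2, 6):
        amp = rng.normal(0.0, roughness / h)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        radii += amp * np.cos(h * theta + phase)
    radii = np.clip(radii, 0.2, None)
    poly = Polygon(np.column_stack((radii * np.cos(theta), radii * np.sin(theta))))
    if not poly.is_valid or poly.area <= 0:  # extreme roughness; retry convex
        poly = Point(0, 0).buffer(1.0, quad_segs=n_vertices // 4)
    scale = math.sqrt(area / poly.area)
    return affinity.scale(poly, xfact=scale, yfact=scale, origin=(0, 0))


def generate_references(spec: SceneSpec) -> ReferenceSet:
    """Place non-overlapping shrub canopies in the plot by rejection sampling."""
    rng = np.random.default_rng(spec.seed)
    width, height = spec.plot_size
    lo, hi = spec.canopy_area_range
    placed: list[Polygon] = []
    attempts = 0
    max_attempts = 200 * max(spec.n_shrubs, 1)
    while len(placed) < spec.n_shrubs:
        if attempts >= max_attempts:
            raise SpecError(
                f"could not place {spec.n_shrubs} shrubs with gap "
                f"{spec.min_gap} m in a {width} x {height} m plot "
                f"({len(placed)} placed after {attempts} attempts)"
            )
        attempts += 1
        area = rng.uniform(lo, hi)
        outline = _star_polygon(rng, area, spec.roughness, spec.n_vertices)
        cx = rng.uniform(0, width)
        cy = rng.uniform(0, height)
        candidate = affinity.translate(outline, xoff=cx, yoff=cy)
        minx, miny, maxx, maxy = candidate.bounds
        if minx < 0 or miny < 0 or maxx > width or maxy > height:
            continue
        if any(candidate.distance(p) < spec.min_gap for p in placed):
            continue
        placed.append(candidate)
    return ReferenceSet([SegmentPolygon(i + 1, g) for i, g in enumerate(placed)])


def render_scene(refs: ReferenceSet, spec: SceneSpec) -> RasterScene:
    """Rasterise references into an RGB scene (pixel-centre majority rule)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    width, height = spec.plot_size
    cols = int(round(width / spec.resolution))
    rows = int(round(height / spec.resolution))
    blank = RasterScene(
        np.zeros((rows, cols, 3), dtype=np.uint8), spec.resolution, (0.0, 0.0)
    )
    labels = rasterize(refs.polygons, blank).labels
    shrub_mask = labels > 0
    img = np.empty((rows, cols, 3), dtype=np.float64)
    img[:] = spec.soil_color
    img[shrub_mask] = spec.shrub_color
    if spec.background_texture > 0:
        # smooth large-scale soil brightness variation
        fx, fy = rng.uniform(0.5, 2.0, size=2)
        px, py = rng.uniform(0, 2 * math.pi, size=2)
        yy, xx = np.mgrid[0:rows, 0:cols]
        tex = np.sin(2 * math.pi * fx * xx / cols + px) * np.sin(
            2 * math.pi * fy * yy / rows + py
        )
        img[~shrub_mask] += (spec.background_texture * tex)[~shrub_mask, None]
    img += rng.normal(0.0, spec.color_sigma, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RasterScene(pixels, spec.resolution, (0.0, 0.0))


def generate_scene(spec: SceneSpec) -> tuple[RasterScene, ReferenceSet]:
    """Generate a plot: reproducible raster plus its ground-truth polygons."""
    refs = generate_references(spec)
    scene = render_scene(refs, spec)
    return scene, refs


# ---------------------------------------------------------------------------
# perturbation models
# ---------------------------------------------------------------------------


def _perturb_one(
    geom: Polygon, mode: str, magnitude: float, rng: np.random.Generator
) -> list[Polygon]:
    if mode == "dilate":
        return [geom.buffer(magnitude, quad_segs=16)]
    if mode == "erode":
        g = geom.buffer(-magnitude, quad_segs=16)
        if g.is_empty:
            return []
        if g.geom_type == "MultiPolygon":
            g = max(g.geoms, key=lambda p: p.area)
        return [g]
    if mode == "shift":
        ang = rng.uniform(0, 2 * math.pi)
        return [
            affinity.translate(
                geom, xoff=magnitude * math.cos(ang), yoff=magnitude * math.sin(ang)
            )
        ]
    if mode == "smooth-boundary":
        g = geom.buffer(magnitude, quad_segs=16).buffer(-magnitude, quad_segs=16)
        return [g] if not g.is_empty else [geom]
    if mode == "split":
        minx, miny, maxx, maxy = geom.bounds
        cx, cy = geom.centroid.x, geom.centroid.y
        ang = rng.uniform(0, math.pi)
        span = 2 * max(maxx - minx, maxy - miny)
        cutter = LineString(
            [
                (cx - span * math.cos(ang), cy - span * math.sin(ang)),
                (cx + span * math.cos(ang), cy + span * math.sin(ang)),
            ]
        )
        pieces = [
            g
            for g in shapely_split(geom, cutter).geoms
            if isinstance(g, Polygon) and g.area > 1e-6
        ]
        return pieces or [geom]
    raise SpecError(f"mode {mode!r} is not an element-wise perturbation")


def perturb_segmentation(refs: ReferenceSet, spec: PerturbSpec) -> SegmentationSet:
    """Degrade a reference set into a candidate segmentation.

    The output carries provenance describing the error mode, so accuracy
    differences measured downstream can be traced to the perturbation that
    caused them.
    """
    rng = np.random.default_rng(spec.seed)
    geoms: list[Polygon] = []
    source = list(refs)

    if spec.mode == "drop":
        for poly in source:
            if rng.uniform() >= spec.probability:
                geoms.append(poly.geometry)
    elif spec.mode == "spurious":
        geoms = [p.geometry for p in source]
        bounds = unary_union([p.geometry for p in source]).bounds
        n_extra = int(round(spec.probability * len(source)))
        radius = max(spec.magnitude, 0.5)
        for _ in range(n_extra):
            cx = rng.uniform(bounds[0], bounds[2])
            cy = rng.uniform(bounds[1], bounds[3])
            geoms.append(Point(cx, cy).buffer(radius, quad_segs=8))
    elif spec.mode == "merge":
        pool = {p.id: p.geometry for p in source}
        ids = sorted(pool)
        for pid in ids:
            if pid not in pool or len(pool) < 2:
                continue
            if rng.uniform() >= spec.probability:
                continue
            others = [k for k in pool if k != pid]
            nearest = min(others, key=lambda k: pool[pid].distance(pool[k]))
            merged = unary_union([pool[pid], pool[nearest]]).convex_hull
            del pool[nearest]
            pool[pid] = merged
        geoms = [pool[k] for k in sorted(pool)]
    else:
        for poly in source:
            if rng.uniform() < spec.probability:
                geoms.extend(
                    _perturb_one(poly.geometry, spec.mode, spec.magnitude, rng)
                )
            else:
                geoms.append(poly.geometry)

    provenance = {
        "method": "perturbation",
        "mode": spec.mode,
        "magnitude": spec.magnitude,
        "probability": spec.probability,
        "seed": spec.seed,
    }
    return SegmentationSet.from_geometries(geoms, provenance)


def make_method_pair(
    refs: ReferenceSet, obia_spec: PerturbSpec, cnn_spec: PerturbSpec
) -> tuple[SegmentationSet, SegmentationSet]:
    """Two candidate segmentations with independent error modes.

    Stands in for the region-merging and CNN outputs of a real pipeline when
    exercising fusion; independence comes from the two specs' seeds.
    """
    if obia_spec.seed == cnn_spec.seed:
        cnn_spec = replace(cnn_spec, seed=cnn_spec.seed + 1_000_003)
    return (
        perturb_segmentation(refs, obia_spec),
        perturb_segmentation(refs, cnn_spec),
    )
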