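"""Multiresolution-style region-merging segmentation.

Bottom-up segmentation controlled by three parameters — Scale, Shape and
Compactness — in the sense used throughout object-based image analysis:
pixels start as singleton regions and adjacent regions are merged while the
heterogeneity increase caused by the cheapest admissible merge stays below
``scale**2``.

The merge criterion is the classic colour/shape trade-off:

    f = (1 - shape) * h_colour + shape * h_shape

where ``h_colour`` is the band-weighted increase in total squared deviation
(sum over pixels of squared distance to the region mean) caused by the merge,
and ``h_shape`` blends a compactness deviation (perimeter * sqrt(n), i.e.
n * perimeter/sqrt(n)) with a smoothness deviation (n * perimeter / bounding
box perimeter), each as merged-minus-parts:

    h_shape = compactness * h_cmpct + (1 - compactness) * h_smooth

Merging follows the globally cheapest admissible pair first, with ties broken
by the lowest (row-major) region labels.  This ordering is deterministic and
yields nested partitions across Scale: the merge trace of a scene depends only
on Shape/Compactness, and the segmentation at any Scale is a prefix of that
trace.  :func:`merge_trace` exposes the trace so parameter sweeps can cut it
at every Scale instead of re-segmenting from scratch.

Geometry bookkeeping is done in pixel units (counts and pixel-edge lengths),
which makes the criterion independent of ground resolution; the Scale
parameter therefore plays the same role at 0.5, 0.1 and 0.03 m/pixel.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, SpecError
from .geometry import LabelMap, RasterScene


@dataclass(frozen=True)
class MRSParams:
    """Scale/Shape/Compactness parameters of the region-merging criterion.

    scale:
        Heterogeneity threshold; a merge executes only while the cheapest
        merge cost is below ``scale**2``.  Larger values give larger segments.
    shape:
        Weight of the shape term against the colour term, in [0, 1).
    compactness:
        Weight of the compactness deviation against boundary smoothness
        inside the shape term, in [0, 1].
    band_weights:
        Per-band non-negative weights, normalised to sum to 1.
    """

    scale: float
    shape: float = 0.1
    compactness: float = 0.5
    band_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise SpecError(f"scale must be > 0, got {self.scale}")
        if not (0 <= self.shape < 1):
            raise SpecError(f"shape must be in [0, 1), got {self.shape}")
        if not (0 <= self.compactness <= 1):
            raise SpecError(f"compactness must be in [0, 1], got {self.compactness}")
        w = tuple(float(x) for x in self.band_weights)
        if len(w) != 3 or any(x < 0 for x in w) or sum(w) <= 0:
            raise SpecError(f"invalid band weights {self.band_weights}")
        s = sum(w)
        object.__setattr__(self, "band_weights", tuple(x / s for x in w))


@dataclass
class Region:
    """Sufficient statistics of one region, in pixel units.

    ``bbox`` is (min_row, min_col, max_row, max_col), inclusive pixel indices;
    ``perimeter`` counts pixel edges on the region boundary.
    """

    n: int
    sums: tuple[float, float, float]
    sumsqs: tuple[float, float, float]
    perimeter: float
    bbox: tuple[int, int, int, int]

    @property
    def bbox_perimeter(self) -> float:
        r0, c0, r1, c1 = self.bbox
        return 2.0 * ((r1 - r0 + 1) + (c1 - c0 + 1))


def merge_cost(
    r1: Region, r2: Region, params: MRSParams, shared_boundary: float
) -> float:
    """Heterogeneity increase caused by merging two adjacent regions.

    ``shared_boundary`` is the length (pixel edges) of the common boundary,
    needed to compute the merged perimeter.  The raw criterion can be negative
    when a merge improves compactness; it is clamped at zero.
    """
    n1, n2 = r1.n, r2.n
    nm = n1 + n2
    h_colour = 0.0
    for b in range(3):
        s1, s2 = r1.sums[b], r2.sums[b]
        q1, q2 = r1.sumsqs[b], r2.sumsqs[b]
        ssd_m = (q1 + q2) - (s1 + s2) ** 2 / nm
        ssd_1 = q1 - s1 * s1 / n1
        ssd_2 = q2 - s2 * s2 / n2
        h_colour += params.band_weights[b] * (ssd_m - ssd_1 - ssd_2)

    lm = r1.perimeter + r2.perimeter - 2.0 * shared_boundary
    a0, b0, a1, b1 = r1.bbox
    c0, d0, c1, d1 = r2.bbox
    mb = (min(a0, c0), min(b0, d0), max(a1, c1), max(b1, d1))
    bm = 2.0 * ((mb[2] - mb[0] + 1) + (mb[3] - mb[1] + 1))
    h_cmpct = lm * math.sqrt(nm) - (
        r1.perimeter * math.sqrt(n1) + r2.perimeter * math.sqrt(n2)
    )
    h_smooth = nm * lm / bm - (
        n1 * r1.perimeter / r1.bbox_perimeter + n2 * r2.perimeter / r2.bbox_perimeter
    )
    h_shape = params.compactness * h_cmpct + (1.0 - params.compactness) * h_smooth
    f = (1.0 - params.shape) * h_colour + params.shape * h_shape
    return f if f > 0.0 else 0.0


@dataclass
class MergeTrace:
    """Full merge history of a scene for fixed Shape/Compactness weights.

    ``merges`` lists (cost, keep, gone) triples in execution order, where
    ``keep``/``gone`` are row-major pixel indices of the two region roots at
    merge time (the surviving root is always the smaller index).  Cutting the
    trace at the first cost >= scale**2 reproduces ``segment`` at that Scale.
    """

    shape: float
    compactness: float
    band_weights: tuple[float, float, float]
    rows: int
    cols: int
    merges: list = field(default_factory=list)

    def cut(self, scale: float) -> LabelMap:
        """Partition of the scene at the given Scale (prefix of the trace)."""
        if not (scale > 0):
            raise SpecError(f"scale must be > 0, got {scale}")
        n = self.rows * self.cols
        parent = np.arange(n, dtype=np.int64)
        threshold = scale * scale
        for cost, keep, gone in self.merges:
            if cost >= threshold:
                break
            parent[gone] = keep
        # resolve chains (each gone index points to a then-root; roots only
        # ever point to smaller indices, so a forward scan resolves fully)
        for idx in range(n):
            p = parent[idx]
            if parent[p] != p:
                parent[idx] = parent[p]
        return _relabel(parent, self.rows, self.cols)

    def segment_counts(self, scales) -> list[int]:
        """Number of segments at each Scale (cheap, no label map built)."""
        costs = [m[0] for m in self.merges]
        n = self.rows * self.cols
        out = []
        for s in scales:
            t = s * s
            k = 0
            for c in costs:
                if c >= t:
                    break
                k += 1
            out.append(n - k)
        return out


def _relabel(parent: np.ndarray, rows: int, cols: int) -> LabelMap:
    """Root indices -> compact labels 1..k in row-major first-occurrence order."""
    roots = parent
    labels = np.zeros(roots.size, dtype=np.int32)
    mapping: dict[int, int] = {}
    nxt = 1
    for idx in range(roots.size):
        r = int(roots[idx])
        lab = mapping.get(r)
        if lab is None:
            lab = mapping[r] = nxt
            nxt += 1
        labels[idx] = lab
    return LabelMap(labels.reshape(rows, cols))


def _run_engine(
    scene: RasterScene,
    params: MRSParams,
    threshold: float | None,
):
    """Greedy globally-cheapest-first merging.

    Returns (parent array, merge list).  ``threshold`` of None runs the merge
    to completion (single region per connected component) for trace recording.
    """
    px = np.asarray(scene.pixels, dtype=np.float64)
    if not np.isfinite(px).all():
        raise DataError("scene pixels contain non-finite values")
    rows, cols = px.shape[:2]
    n = rows * cols
    flat = px.reshape(n, 3)

    w0, w1, w2 = params.band_weights
    shape_w = params.shape
    colour_w = 1.0 - shape_w
    cmp_w = params.compactness
    smooth_w = 1.0 - cmp_w

    cnt = [1] * n
    s0 = flat[:, 0].tolist()
    s1 = flat[:, 1].tolist()
    s2 = flat[:, 2].tolist()
    q0 = (flat[:, 0] ** 2).tolist()
    q1 = (flat[:, 1] ** 2).tolist()
    q2 = (flat[:, 2] ** 2).tolist()
    perim = [4.0] * n
    minr = (np.arange(n) // cols).tolist()
    maxr = minr[:]
    minc = (np.arange(n) % cols).tolist()
    maxc = minc[:]
    alive = [True] * n
    version = [0] * n
    adj: list[dict[int, float]] = [dict() for _ in range(n)]

    sqrt = math.sqrt

    def cost_of(i: int, j: int) -> float:
        ni, nj = cnt[i], cnt[j]
        nm = ni + nj
        si0, sj0 = s0[i], s0[j]
        si1, sj1 = s1[i], s1[j]
        si2, sj2 = s2[i], s2[j]
        h = w0 * ((q0[i] + q0[j]) - (si0 + sj0) ** 2 / nm - (q0[i] - si0 * si0 / ni) - (q0[j] - sj0 * sj0 / nj))
        h += w1 * ((q1[i] + q1[j]) - (si1 + sj1) ** 2 / nm - (q1[i] - si1 * si1 / ni) - (q1[j] - sj1 * sj1 / nj))
        h += w2 * ((q2[i] + q2[j]) - (si2 + sj2) ** 2 / nm - (q2[i] - si2 * si2 / ni) - (q2[j] - sj2 * sj2 / nj))
        if shape_w > 0.0:
            li, lj = perim[i], perim[j]
            lm = li + lj - 2.0 * adj[i][j]
            mr0 = minr[i] if minr[i] < minr[j] else minr[j]
            mc0 = minc[i] if minc[i] < minc[j] else minc[j]
            mr1 = maxr[i] if maxr[i] > maxr[j] else maxr[j]
            mc1 = maxc[i] if maxc[i] > maxc[j] else maxc[j]
            bm = 2.0 * ((mr1 - mr0 + 1) + (mc1 - mc0 + 1))
            bi = 2.0 * ((maxr[i] - minr[i] + 1) + (maxc[i] - minc[i] + 1))
            bj = 2.0 * ((maxr[j] - minr[j] + 1) + (maxc[j] - minc[j] + 1))
            h_cmpct = lm * sqrt(nm) - (li * sqrt(ni) + lj * sqrt(nj))
            h_smooth = nm * lm / bm - (ni * li / bi + nj * lj / bj)
            f = colour_w * h + shape_w * (cmp_w * h_cmpct + smooth_w * h_smooth)
        else:
            f = colour_w * h
        return f if f > 0.0 else 0.0

    heap: list[tuple] = []
    push = heapq.heappush
    # initial 4-neighbour adjacency
    for r in range(rows):
        base = r * cols
        for c in range(cols):
            i = base + c
            if c + 1 < cols:
                adj[i][i + 1] = 1.0
                adj[i + 1][i] = 1.0
            if r + 1 < rows:
                adj[i][i + cols] = 1.0
                adj[i + cols][i] = 1.0
    for i in range(n):
        for j in adj[i]:
            if j > i:
                heap.append((cost_of(i, j), i, j, 0, 0))
    heapq.heapify(heap)

    merges: list[tuple[float, int, int]] = []
    parent = np.arange(n, dtype=np.int64)
    pops_since_compact = 0

    while heap:
        cost, i, j, vi, vj = heapq.heappop(heap)
        if not (alive[i] and alive[j]) or version[i] != vi or version[j] != vj:
            pops_since_compact += 1
            if pops_since_compact > 2_000_000:
                heap = [
                    e
                    for e in heap
                    if alive[e[1]] and alive[e[2]]
                    and version[e[1]] == e[3] and version[e[2]] == e[4]
                ]
                heapq.heapify(heap)
                pops_since_compact = 0
            continue
        if threshold is not None and cost >= threshold:
            break
        # merge j into i (i < j always holds for heap entries)
        merges.append((cost, i, j))
        parent[j] = i
        cnt[i] += cnt[j]
        s0[i] += s0[j]; s1[i] += s1[j]; s2[i] += s2[j]
        q0[i] += q0[j]; q1[i] += q1[j]; q2[i] += q2[j]
        perim[i] = perim[i] + perim[j] - 2.0 * adj[i][j]
        if minr[j] < minr[i]: minr[i] = minr[j]
        if minc[j] < minc[i]: minc[i] = minc[j]
        if maxr[j] > maxr[i]: maxr[i] = maxr[j]
        if maxc[j] > maxc[i]: maxc[i] = maxc[j]
        alive[j] = False
        version[i] += 1
        version[j] += 1
        del adj[i][j]
        aj = adj[j]
        ai = adj[i]
        for k, s_jk in aj.items():
            if k == i:
                continue
            ai[k] = ai.get(k, 0.0) + s_jk
            adj[k][i] = ai[k]
            del adj[k][j]
        adj[j] = {}
        for k in ai:
            a, b = (i, k) if i < k else (k, i)
            push(heap, (cost_of(a, b), a, b, version[a], version[b]))

    # resolve union-find chains
    for idx in range(n):
        p = parent[idx]
        while parent[p] != p:
            p = parent[p]
        parent[idx] = p
    return parent, merges


def segment(scene: RasterScene, params: MRSParams) -> LabelMap:
    """Partition a scene into segments at the given Scale/Shape/Compactness.

    Deterministic: identical input always yields the identical label map.
    Labels are 1..k in row-major order of first appearance.
    """
    parent, _ = _run_engine(scene, params, threshold=params.scale**2)
    return _relabel(parent, scene.rows, scene.cols)


def merge_trace(
    scene: RasterScene,
    shape: float = 0.1,
    compactness: float = 0.5,
    band_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> MergeTrace:
    """Record the complete merge history for fixed Shape/Compactness.

    ``trace.cut(scale)`` then equals ``segment(scene, MRSParams(scale, ...))``
    for every Scale, which makes sweeping Scale cheap.
    """
    params = MRSParams(
        scale=1.0, shape=shape, compactness=compactness, band_weights=band_weights
    )
    _, merges = _run_engine(scene, params, threshold=None)
    return MergeTrace(
        shape=shape,
        compactness=compactness,
        band_weights=params.band_weights,
        rows=scene.rows,
        cols=scene.cols,
        merges=merges,
    )
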