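"""Independent brute-force oracles used by the test suite.

These deliberately avoid the data structures of the implementation: the
merging oracle rescans every adjacent region pair at every step, and the
overlap oracle counts sub-pixels on a fine grid.
"""

from __future__ import annotations

import numpy as np

from scrubseg.geometry import LabelMap, RasterScene
from scrubseg.mrs import MRSParams, Region, merge_cost


def oracle_segment(scene: RasterScene, params: MRSParams) -> LabelMap:
    """Greedy cheapest-merge-first segmentation, no shortcuts.

    Every step recomputes the cost of every adjacent region pair with the
    public :func:`scrubseg.mrs.merge_cost`, picks the (cost, label_a,
    label_b) minimum and merges while the cost stays below scale**2.
    """
    px = np.asarray(scene.pixels, dtype=np.float64)
    rows, cols = px.shape[:2]
    n = rows * cols

    regions: dict[int, Region] = {}
    members: dict[int, list[int]] = {}
    for idx in range(n):
        r, c = divmod(idx, cols)
        v = px[r, c]
        regions[idx] = Region(
            n=1,
            sums=(v[0], v[1], v[2]),
            sumsqs=(v[0] ** 2, v[1] ** 2, v[2] ** 2),
            perimeter=4.0,
            bbox=(r, c, r, c),
        )
        members[idx] = [idx]

    shared: dict[tuple[int, int], float] = {}
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                shared[(i, i + 1)] = 1.0
            if r + 1 < rows:
                shared[(i, i + cols)] = 1.0

    threshold = params.scale**2
    while True:
        best = None
        for (i, j), s in shared.items():
            cost = merge_cost(regions[i], regions[j], params, s)
            key = (cost, i, j)
            if best is None or key < best:
                best = key
        if best is None or best[0] >= threshold:
            break
        _, i, j = best
        ri, rj = regions[i], regions[j]
        s_ij = shared.pop((i, j))
        regions[i] = Region(
            n=ri.n + rj.n,
            sums=tuple(a + b for a, b in zip(ri.sums, rj.sums)),
            sumsqs=tuple(a + b for a, b in zip(ri.sumsqs, rj.sumsqs)),
            perimeter=ri.perimeter + rj.perimeter - 2.0 * s_ij,
            bbox=(
                min(ri.bbox[0], rj.bbox[0]),
                min(ri.bbox[1], rj.bbox[1]),
                max(ri.bbox[2], rj.bbox[2]),
                max(ri.bbox[3], rj.bbox[3]),
            ),
        )
        members[i].extend(members.pop(j))
        del regions[j]
        # reconnect j's neighbours to i
        for (a, b) in list(shared):
            if j in (a, b):
                s = shared.pop((a, b))
                k = b if a == j else a
                key = (min(i, k), max(i, k))
                shared[key] = shared.get(key, 0.0) + s

    labels = np.zeros(n, dtype=np.int32)
    nxt = 1
    for idx in range(n):
        if labels[idx]:
            continue
        root = next(k for k, pix in members.items() if idx in pix)
        for p in members[root]:
            labels[p] = nxt
        nxt += 1
    return LabelMap(labels.reshape(rows, cols))


def pixel_overlap_area(geom_a, geom_b, subdiv: int = 200) -> float:
    """Intersection area by counting sub-pixel centres on a fine grid."""
    import shapely

    minx = min(geom_a.bounds[0], geom_b.bounds[0])
    miny = min(geom_a.bounds[1], geom_b.bounds[1])
    maxx = max(geom_a.bounds[2], geom_b.bounds[2])
    maxy = max(geom_a.bounds[3], geom_b.bounds[3])
    xs = np.linspace(minx, maxx, subdiv, endpoint=False) + (maxx - minx) / subdiv / 2
    ys = np.linspace(miny, maxy, subdiv, endpoint=False) + (maxy - miny) / subdiv / 2
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom_a, xx.ravel(), yy.ravel()) & shapely.contains_xy(
        geom_b, xx.ravel(), yy.ravel()
    )
    cell = ((maxx - minx) / subdiv) * ((maxy - miny) / subdiv)
    return float(inside.sum() * cell)
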