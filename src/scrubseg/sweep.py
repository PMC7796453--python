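"""Exhaustive Scale/Shape/Compactness parameter sweep (SPR).

The segmentation-parameters-range procedure evaluates every combination on a
regular grid — Scale in steps of 5 over [80, 430] and Shape/Compactness in
steps of 0.1 over [0.1, 0.9] by default — scores each candidate segmentation
against the reference polygons by ED2, and selects the combination with the
lowest ED2 (ties break towards lower Scale, then Shape, then Compactness).

Because the merge order used by :mod:`scrubseg.mrs` is independent of Scale,
the sweep records one merge trace per (Shape, Compactness) pair and cuts it
at every Scale value, which is equivalent to — and much cheaper than —
segmenting from scratch at every grid point.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import pandas as pd

from .errors import SpecError
from .geometry import RasterScene, ReferenceSet, polygonize
from .metrics import evaluate
from .mrs import MRSParams, merge_trace

#: Global admissible Scale range used when clamping size-derived bounds.
GLOBAL_SCALE_RANGE = (80.0, 430.0)


@dataclass(frozen=True)
class SweepSpec:
    """Inclusive (min, max, step) ranges for the three parameters."""

    scale_range: tuple[float, float, float] = (80.0, 430.0, 5.0)
    shape_range: tuple[float, float, float] = (0.1, 0.9, 0.1)
    compactness_range: tuple[float, float, float] = (0.1, 0.9, 0.1)

    def __post_init__(self) -> None:
        for name in ("scale_range", "shape_range", "compactness_range"):
            lo, hi, step = getattr(self, name)
            if step <= 0:
                raise SpecError(f"{name}: step must be > 0")
            if lo > hi:
                raise SpecError(f"{name}: min must be <= max")


def _axis_values(lo: float, hi: float, step: float) -> list[float]:
    count = int(round((hi - lo) / step)) + 1
    vals = [round(lo + i * step, 10) for i in range(count)]
    return [v for v in vals if v <= hi + 1e-9]


def enumerate_grid(spec: SweepSpec) -> list[MRSParams]:
    """All grid combinations in lexicographic (scale, shape, compactness) order."""
    scales = _axis_values(*spec.scale_range)
    shapes = _axis_values(*spec.shape_range)
    compacts = _axis_values(*spec.compactness_range)
    if not (scales and shapes and compacts):
        raise SpecError("sweep grid is empty")
    return [
        MRSParams(scale=sc, shape=sh, compactness=cp)
        for sc in scales
        for sh in shapes
        for cp in compacts
    ]


@dataclass
class SweepResult:
    """Sweep table sorted by ED2 (ascending) plus the winning row."""

    table: pd.DataFrame
    best: dict

    @property
    def best_params(self) -> MRSParams:
        return MRSParams(
            scale=self.best["scale"],
            shape=self.best["shape"],
            compactness=self.best["compactness"],
        )


def run_sweep(
    scene: RasterScene,
    spec: SweepSpec,
    refs: ReferenceSet,
    iou_threshold: float = 0.5,
    correspondence_threshold: float = 0.05,
) -> SweepResult:
    """Evaluate every grid point against the references and rank by ED2.

    Deterministic: the result is independent of evaluation order, and ties
    in ED2 resolve to the lexicographically smallest parameters.
    """
    scales = _axis_values(*spec.scale_range)
    shapes = _axis_values(*spec.shape_range)
    compacts = _axis_values(*spec.compactness_range)
    if not (scales and shapes and compacts):
        raise SpecError("sweep grid is empty")

    rows = []
    for sh in shapes:
        for cp in compacts:
            t0 = time.perf_counter()
            trace = merge_trace(scene, shape=sh, compactness=cp)
            trace_time = time.perf_counter() - t0
            for sc in scales:
                t1 = time.perf_counter()
                try:
                    label_map = trace.cut(sc)
                    segs = polygonize(label_map, scene)
                    report = evaluate(
                        segs,
                        refs,
                        iou_threshold=iou_threshold,
                        correspondence_threshold=correspondence_threshold,
                    )
                except Exception as exc:
                    raise type(exc)(
                        f"scale={sc} shape={sh} compactness={cp}: {exc}"
                    ) from exc
                rows.append(
                    {
                        "scale": sc,
                        "shape": sh,
                        "compactness": cp,
                        "pse": report.pse,
                        "nsr": report.nsr,
                        "ed2": report.ed2,
                        "n_segments": len(segs),
                        "runtime_s": (time.perf_counter() - t1)
                        + trace_time / len(scales),
                    }
                )
    table = pd.DataFrame(rows).sort_values(
        by=["ed2", "scale", "shape", "compactness"], kind="mergesort"
    )
    table = table.reset_index(drop=True)
    best = table.iloc[0].to_dict()
    return SweepResult(table=table, best=best)


def scale_bounds_from_object_size(
    min_area: float,
    max_area: float,
    resolution: float,
    clamp: tuple[float, float] = GLOBAL_SCALE_RANGE,
) -> tuple[float, float]:
    """Admissible Scale band implied by the object sizes to segment.

    The Scale parameter tracks object size in pixels, so the bounds grow as
    sqrt(area)/resolution (the object's linear size in pixels) and are then
    clamped to the global admissible range.  Finer resolution (smaller
    m/pixel) therefore yields larger bounds.
    """
    if min_area <= 0 or max_area <= 0 or resolution <= 0:
        raise SpecError("areas and resolution must be positive")
    if min_area > max_area:
        raise SpecError("min_area must be <= max_area")
    lo = min_area**0.5 / resolution
    hi = max_area**0.5 / resolution
    c0, c1 = clamp
    return (min(max(lo, c0), c1), min(max(hi, c0), c1))
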