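from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pytest
from shapely.geometry import box

from scrubseg.geometry import (
    RasterScene,
    ReferenceSet,
    SegmentPolygon,
    SegmentationSet,
)

DATA_DIR = Path(__file__).parent / "data"


def square(pid: int, x: float, y: float, side: float = 1.0) -> SegmentPolygon:
    """Axis-aligned square segment with lower corner at (x, y)."""
    return SegmentPolygon(pid, box(x, y, x + side, y + side))


def seg_set(*polys: SegmentPolygon, **prov) -> SegmentationSet:
    return SegmentationSet(list(polys), provenance=prov)


def ref_set(*polys: SegmentPolygon) -> ReferenceSet:
    return ReferenceSet(list(polys))


def random_scene(rng: np.random.Generator, rows: int, cols: int) -> RasterScene:
    """Uniform random RGB noise scene at 1 m/pixel."""
    px = rng.integers(0, 256, size=(rows, cols, 3), dtype=np.int64).astype(np.uint8)
    return RasterScene(px, 1.0)


@pytest.fixture(scope="session")
def detection_benchmark() -> list[dict]:
    """Published detection counts/scores (54 experiment-image rows)."""
    rows = []
    with open(DATA_DIR / "detection_benchmark.csv") as fh:
        reader = csv.DictReader(
            line for line in fh if not line.startswith("#")
        )
        for row in reader:
            rows.append(
                {
                    "experiment": row["experiment"],
                    "image": row["image"],
                    "tp": int(row["tp"]),
                    "fp": int(row["fp"]),
                    "fn": int(row["fn"]),
                    "precision": float(row["precision"]),
                    "recall": float(row["recall"]),
                    "f1": float(row["f1"]),
                    "inconsistent": bool(int(row["inconsistent"])),
                }
            )
    assert len(rows) == 54
    return rows


@pytest.fixture(scope="session")
def segmentation_benchmark() -> list[dict]:
    """Published PSE/NSR/ED2 triples for the six best experiments."""
    rows = []
    with open(DATA_DIR / "segmentation_benchmark.csv") as fh:
        reader = csv.DictReader(
            line for line in fh if not line.startswith("#")
        )
        for row in reader:
            rows.append(
                {
                    "experiment": row["experiment"],
                    "pse": float(row["pse"]),
                    "nsr": float(row["nsr"]),
                    "ed2": float(row["ed2"]),
                }
            )
    assert len(rows) == 6
    return rows
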