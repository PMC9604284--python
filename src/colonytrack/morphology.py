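"""Colony-level shape and motion metrics.

Shape of a colony is summarized by its area S (µm²), perimeter P (µm) and
circularity 4πS/P² — 1 for a perfect circle, tending to 0 as the colony
elongates. Colony motion is summarized by the center of mass, the per-frame
unweighted mean of all tracked cell positions, rebased so the path starts at
(0, 0).

The perimeter is measured on the sub-pixel marching-squares contour of the
label at iso-level 0.5 (all contours of the label summed, so internal holes
contribute). Pixel-edge counting would systematically overestimate P and cap
disk circularity near 0.79, contradicting the "perfect circle = 1" reading;
the contour estimate converges to the true perimeter as resolution grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .errors import (
    DomainError,
    EmptyInputError,
    InsufficientDataError,
    NotFoundError,
)
from .io import ColonyMaskStack, TrackSet

__all__ = [
    "ColonyShapeRecord",
    "CentroidPath",
    "colony_area",
    "colony_perimeter",
    "circularity",
    "shape_timeseries",
    "shape_table",
    "compare_endpoint_circularity",
    "center_of_mass",
    "centroid_path",
]


@dataclass(frozen=True)
class ColonyShapeRecord:
    """Shape descriptors of one colony at one frame."""

    frame: int
    time_h: float
    area_um2: float
    perimeter_um: float
    circularity: float


@dataclass(frozen=True)
class CentroidPath:
    """Center-of-mass trajectory rebased to start at the origin.

    ``times_h`` are hours; ``xy`` is (n, 2) µm with ``xy[0] == (0, 0)``.
    """

    times_h: np.ndarray
    xy: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times_h, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape != (times.shape[0], 2):
            raise ValueError("xy must be (n, 2) matching times_h")
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "xy", xy)

    def __len__(self) -> int:
        return int(self.times_h.shape[0])


def colony_area(mask: np.ndarray, label: int, pixel_size: float) -> float:
    """Area of ``label`` in µm²: pixel count × pixel_size²."""
    mask = np.asarray(mask)
    count = int(np.count_nonzero(mask == label))
    if count == 0:
        raise NotFoundError(f"label {label} not present in mask")
    return count * pixel_size**2


def colony_perimeter(mask: np.ndarray, label: int, pixel_size: float) -> float:
    """Perimeter of ``label`` in µm from the marching-squares contour.

    Sums the lengths of every 0.5-level contour of the label (outer boundary
    plus any hole boundaries). A single isolated pixel yields a small positive
    perimeter, not zero.
    """
    mask = np.asarray(mask)
    binary = (mask == label)
    if not binary.any():
        raise NotFoundError(f"label {label} not present in mask")
    # pad so contours of blobs touching the border still close
    padded = np.pad(binary, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    total = 0.0
    for contour in contours:
        total += _closed_contour_length(contour)
    return total * pixel_size


def _closed_contour_length(contour: np.ndarray, window: int = 5) -> float:
    """Length of a closed marching-squares contour after light smoothing.

    The raw 0.5-level contour of a binary image staircases along the pixel
    grid and overestimates the length of a smooth boundary by a few percent
    (≈7% for a disk). A short periodic moving average over the vertices
    removes the zigzag while preserving shape at scales above ~2 px, giving
    sub-percent perimeter error for rasterized smooth shapes; tiny blobs
    shrink but keep a positive length.
    """
    pts = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    n = pts.shape[0]
    if n < 3:
        return float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    w = min(window, n if n % 2 else n - 1)
    kernel = np.ones(w) / w
    smooth = np.column_stack(
        [np.convolve(np.r_[pts[-(w // 2):, k], pts[:, k], pts[: w // 2, k]], kernel, mode="valid")
         for k in range(2)]
    )
    closed = np.vstack([smooth, smooth[:1]])
    return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))


def circularity(area_um2: float, perimeter_um: float) -> float:
    """Circularity 4πS/P²; 1 for a circle, → 0 for elongated shapes."""
    if not (area_um2 > 0 and perimeter_um > 0):
        raise DomainError("area and perimeter must be positive")
    return 4.0 * np.pi * area_um2 / perimeter_um**2


def shape_timeseries(
    stack: ColonyMaskStack, label: int
) -> list[ColonyShapeRecord | None]:
    """Per-frame shape records for ``label``; ``None`` where the label is absent.

    Frames without the label yield missing records, never zeros, so downstream
    statistics do not mistake absence for a degenerate shape.
    """
    records: list[ColonyShapeRecord | None] = []
    found = False
    for k in range(len(stack)):
        page = stack.masks[k]
        if not (page == label).any():
            records.append(None)
            continue
        found = True
        area = colony_area(page, label, stack.pixel_size)
        perim = colony_perimeter(page, label, stack.pixel_size)
        records.append(
            ColonyShapeRecord(
                frame=k,
                time_h=k * stack.frame_interval / 60.0,
                area_um2=area,
                perimeter_um=perim,
                circularity=circularity(area, perim),
            )
        )
    if not found:
        raise NotFoundError(f"label {label} absent from every frame")
    return records


def shape_table(stack: ColonyMaskStack, label: int, colony_id: str = "colony") -> pd.DataFrame:
    """Shape time-series as a tidy table (missing frames omitted)."""
    rows = [
        {
            "colony_id": colony_id,
            "frame": r.frame,
            "time_h": r.time_h,
            "area_um2": r.area_um2,
            "perimeter_um": r.perimeter_um,
            "circularity": r.circularity,
        }
        for r in shape_timeseries(stack, label)
        if r is not None
    ]
    return pd.DataFrame(
        rows, columns=["colony_id", "frame", "time_h", "area_um2", "perimeter_um", "circularity"]
    )


def compare_endpoint_circularity(
    records_per_colony: Sequence[Sequence[ColonyShapeRecord | None]],
    t0: float,
    t1: float,
    method: str = "wilcoxon",
) -> dict:
    """Paired comparison of colony circularity between two time points.

    For each colony the record nearest to ``t0`` and ``t1`` (hours) is taken;
    the per-colony differences (t1 − t0) enter a paired two-sided test —
    Wilcoxon signed-rank by default (robust at small n), paired t-test via
    ``method='ttest'``. All-zero differences return p = 1 by convention.
    """
    if method not in ("wilcoxon", "ttest"):
        raise DomainError(f"unknown method {method!r}")
    pairs = []
    for records in records_per_colony:
        present = [r for r in records if r is not None]
        if not present:
            continue
        times = np.array([r.time_h for r in present])
        c0 = present[int(np.argmin(np.abs(times - t0)))].circularity
        c1 = present[int(np.argmin(np.abs(times - t1)))].circularity
        pairs.append((c0, c1))
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >=3 colonies with records at both time points, got {len(pairs)}"
        )
    c0s = np.array([p[0] for p in pairs])
    c1s = np.array([p[1] for p in pairs])
    diffs = c1s - c0s
    if np.allclose(diffs, 0.0):
        statistic, pvalue = 0.0, 1.0
    elif method == "wilcoxon":
        res = stats.wilcoxon(diffs, alternative="two-sided")
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    else:
        res = stats.ttest_rel(c1s, c0s)
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    return {
        "n": len(pairs),
        "t0_h": t0,
        "t1_h": t1,
        "mean_t0": float(c0s.mean()),
        "sd_t0": float(c0s.std(ddof=1)),
        "mean_t1": float(c1s.mean()),
        "sd_t1": float(c1s.std(ddof=1)),
        "mean_difference": float(diffs.mean()),
        "method": method,
        "statistic": statistic,
        "pvalue": pvalue,
    }


def center_of_mass(ts: TrackSet, frame: int) -> np.ndarray:
    """Unweighted mean of all cell positions recorded at ``frame`` (µm).

    Cells in tracking gaps at that frame are excluded, not interpolated.
    """
    pts = ts.positions_at(frame)
    if pts.shape[0] == 0:
        raise NotFoundError(f"no cell positions at frame {frame}")
    return pts.mean(axis=0)


def centroid_path(ts: TrackSet) -> CentroidPath:
    """Center-of-mass trajectory over all frames with ≥1 tracked cell,
    rebased so the first computable centroid is (0, 0)."""
    if len(ts) == 0:
        raise EmptyInputError("empty TrackSet")
    lo, hi = ts.frame_range
    times, points = [], []
    for frame in range(lo, hi + 1):
        pts = ts.positions_at(frame)
        if pts.shape[0] == 0:
            continue
        times.append(frame * ts.frame_interval / 60.0)
        points.append(pts.mean(axis=0))
    xy = np.asarray(points)
    return CentroidPath(times_h=np.asarray(times), xy=xy - xy[0])
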