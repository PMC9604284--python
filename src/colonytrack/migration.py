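"""Per-cell trajectory metrics: straightness, speed, fiber-relative angles.

Definitions
-----------
straightness
    Net Euclidean displacement divided by total path length, in (0, 1]; 1 for
    a straight co-directed track, 0 for a closed loop. Undefined (NaN) for a
    stationary track — a 0/0 ratio — and such cells are excluded from group
    means with an explicit count rather than assigned a value.
mean speed
    Total path length over elapsed time between first and last recorded
    position, in µm/h. With no tracking gaps this equals the mean of per-step
    speeds; with gaps it stays well-defined. Net-displacement speed is also
    exposed (``net_speed``) since either reading of "velocity" is defensible.
direction angle
    For each frame-to-frame step, the unsigned angle in [0°, 180°] between
    the step vector and the axis perpendicular to the fibers (for fibers
    along y the reference is +x). 90° means motion exactly along the fiber.
    Angles are computed per step, not on the whole-track displacement, so one
    cell contributes many angles to a rose plot; 0° and 180° stay distinct
    within the fold to preserve bimodality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DomainError, ConfigError, EmptyInputError, InsufficientDataError
from .io import CellTrack, TrackSet

__all__ = [
    "MigrationMetrics",
    "rebase_trajectory",
    "path_length",
    "net_displacement",
    "straightness",
    "mean_speed",
    "step_direction_angles",
    "whole_track_angle",
    "angle_histogram",
    "track_metrics",
    "metrics_table",
    "summarize_group",
]


@dataclass(frozen=True)
class MigrationMetrics:
    """Scalar migration metrics of one cell, plus its pooled step angles."""

    cell_id: str
    phenotype: str | None
    condition: float | None
    d_total_um: float
    d_euclid_um: float
    straightness: float  # NaN when the cell is stationary
    mean_speed_um_h: float
    net_speed_um_h: float
    step_angles_deg: np.ndarray
    n_steps: int
    n_zero_steps: int


def rebase_trajectory(track: CellTrack) -> CellTrack:
    """Translate a track so its first position is (0, 0); idempotent."""
    if len(track) == 0:
        raise EmptyInputError(f"track {track.cell_id!r} is empty")
    return replace(track, xy=track.xy - track.xy[0])


def _steps(track: CellTrack) -> np.ndarray:
    if len(track) < 2:
        raise InsufficientDataError(
            f"track {track.cell_id!r}: need >=2 positions, have {len(track)}"
        )
    return np.diff(track.xy, axis=0)


def path_length(track: CellTrack) -> float:
    """Total path length d_total (µm): sum of consecutive step lengths.

    Gaps are bridged by a straight segment, the minimal assumption about
    unobserved motion.
    """
    return float(np.hypot(*_steps(track).T).sum())


def net_displacement(track: CellTrack) -> float:
    """Net Euclidean displacement d_euclid (µm), first to last position."""
    if len(track) < 2:
        raise InsufficientDataError(
            f"track {track.cell_id!r}: need >=2 positions, have {len(track)}"
        )
    return float(np.hypot(*(track.xy[-1] - track.xy[0])))


def straightness(track: CellTrack) -> float:
    """d_euclid / d_total in (0, 1]; NaN for a stationary track (0/0)."""
    d_total = path_length(track)
    if d_total == 0.0:
        return float("nan")
    return net_displacement(track) / d_total


def elapsed_hours(track: CellTrack, frame_interval: float) -> float:
    """Elapsed time (h) between first and last recorded position."""
    if len(track) < 2:
        raise InsufficientDataError(
            f"track {track.cell_id!r}: need >=2 positions, have {len(track)}"
        )
    return float(track.frames[-1] - track.frames[0]) * frame_interval / 60.0


def mean_speed(track: CellTrack, frame_interval: float) -> float:
    """Path length over elapsed time, µm/h; robust to tracking gaps."""
    hours = elapsed_hours(track, frame_interval)
    if hours <= 0:
        raise DomainError(f"track {track.cell_id!r}: zero elapsed time")
    return path_length(track) / hours


def _reference_axis(fiber_axis: str) -> np.ndarray:
    # reference is perpendicular to the fibers: +x for fibers along y
    if fiber_axis == "y":
        return np.array([1.0, 0.0])
    if fiber_axis == "x":
        return np.array([0.0, 1.0])
    raise ConfigError(f"fiber_axis must be 'x' or 'y', got {fiber_axis!r}")


def step_direction_angles(track: CellTrack, fiber_axis: str = "y") -> tuple[np.ndarray, int]:
    """Unsigned angles (degrees, [0, 180]) of each nonzero step relative to
    the perpendicular-to-fiber axis; returns ``(angles, n_zero_steps)``.

    Zero-length steps carry no direction and are skipped but counted.
    """
    steps = _steps(track)
    lengths = np.hypot(*steps.T)
    nonzero = lengths > 0
    n_zero = int(np.count_nonzero(~nonzero))
    ref = _reference_axis(fiber_axis)
    cosang = (steps[nonzero] @ ref) / lengths[nonzero]
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angles, n_zero


def whole_track_angle(track: CellTrack, fiber_axis: str = "y") -> float:
    """Direction angle of the whole-track net displacement (secondary
    statistic); NaN for a track that returns exactly to its start."""
    if len(track) < 2:
        raise InsufficientDataError(
            f"track {track.cell_id!r}: need >=2 positions, have {len(track)}"
        )
    net = track.xy[-1] - track.xy[0]
    norm = np.hypot(*net)
    if norm == 0:
        return float("nan")
    ref = _reference_axis(fiber_axis)
    return float(np.degrees(np.arccos(np.clip(net @ ref / norm, -1.0, 1.0))))


def angle_histogram(angles, bin_width: float = 10.0) -> dict:
    """Bin pooled direction angles over [0°, 180°] for a rose plot.

    Bins are ``[0, w), [w, 2w), ..., [180-w, 180]`` (the last bin closed);
    180 must be divisible by ``bin_width``. The per-condition summary is the
    arithmetic mean of the folded angles together with their SD — a mean near
    90° with a small SD signals motion concentrated along the fibers, while a
    mean of 90° with a large SD can also arise from a 0°/180° bimodal pattern,
    which the SD exposes.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise EmptyInputError("no angles to histogram")
    if angles.min() < 0 or angles.max() > 180:
        raise DomainError("angles must lie in [0, 180]")
    if not float(bin_width) > 0 or 180.0 % bin_width != 0:
        raise ConfigError(f"bin_width {bin_width} must evenly divide 180")
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    return {
        "bin_edges_deg": edges,
        "counts": counts,
        "n": int(angles.size),
        "mean_deg": float(angles.mean()),
        "sd_deg": float(angles.std(ddof=1)) if angles.size > 1 else 0.0,
    }


def track_metrics(
    track: CellTrack,
    frame_interval: float,
    fiber_axis: str = "y",
    condition: float | None = None,
) -> MigrationMetrics:
    """All per-cell metrics of one metric-eligible track."""
    d_total = path_length(track)
    d_euclid = net_displacement(track)
    hours = elapsed_hours(track, frame_interval)
    if hours <= 0:
        raise DomainError(f"track {track.cell_id!r}: zero elapsed time")
    angles, n_zero = step_direction_angles(track, fiber_axis)
    return MigrationMetrics(
        cell_id=track.cell_id,
        phenotype=track.phenotype,
        condition=condition,
        d_total_um=d_total,
        d_euclid_um=d_euclid,
        straightness=d_euclid / d_total if d_total > 0 else float("nan"),
        mean_speed_um_h=d_total / hours,
        net_speed_um_h=d_euclid / hours,
        step_angles_deg=angles,
        n_steps=len(track) - 1,
        n_zero_steps=n_zero,
    )


def metrics_table(ts: TrackSet) -> pd.DataFrame:
    """Per-cell metric table for every metric-eligible track of a TrackSet.

    Columns follow the package's export schema; ``step_angles_deg`` is kept
    as an object column of arrays for downstream pooling.
    """
    rows = []
    for track in ts.metric_eligible_tracks:
        m = track_metrics(track, ts.frame_interval, ts.fiber_axis, ts.condition)
        rows.append(
            {
                "cell_id": m.cell_id,
                "phenotype": m.phenotype if m.phenotype is not None else "unlabeled",
                "condition_N": m.condition,
                "d_total_um": m.d_total_um,
                "d_euclid_um": m.d_euclid_um,
                "straightness": m.straightness,
                "mean_speed_um_h": m.mean_speed_um_h,
                "net_speed_um_h": m.net_speed_um_h,
                "n_steps": m.n_steps,
                "n_zero_steps": m.n_zero_steps,
                "step_angles_deg": m.step_angles_deg,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "phenotype",
            "condition_N",
            "d_total_um",
            "d_euclid_um",
            "straightness",
            "mean_speed_um_h",
            "net_speed_um_h",
            "n_steps",
            "n_zero_steps",
            "step_angles_deg",
        ],
    )


def summarize_group(
    metrics: pd.DataFrame,
    by: tuple[str, ...] = ("condition_N", "phenotype"),
    values: tuple[str, ...] = ("straightness", "mean_speed_um_h"),
) -> pd.DataFrame:
    """Mean ± sample SD of per-cell metrics by group (condition × phenotype).

    Cells with an undefined metric (NaN, e.g. stationary cells for
    straightness) are excluded from that metric's mean/SD and counted in
    ``n_undefined_<metric>``. Groups with fewer than 2 defined cells report
    NaN SD; empty groups are omitted.
    """
    if metrics.empty:
        return pd.DataFrame()
    rows = []
    for keys, grp in metrics.groupby(list(by), dropna=False, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(by, keys))
        row["n_cells"] = len(grp)
        for col in values:
            vals = grp[col].to_numpy(dtype=float)
            defined = vals[~np.isnan(vals)]
            row[f"mean_{col}"] = float(defined.mean()) if defined.size else float("nan")
            row[f"sd_{col}"] = (
                float(defined.std(ddof=1)) if defined.size > 1 else float("nan")
            )
            row[f"n_undefined_{col}"] = int(vals.size - defined.size)
        rows.append(row)
    return pd.DataFrame(rows)
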