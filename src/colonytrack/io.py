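"""Reading and writing cell-track tables and colony mask stacks.

Coordinate conventions
----------------------
Positions are physical (µm), origin at the top-left of the imaged field, y
increasing downward (image convention). ``fiber_axis`` names the image axis
the aligned fibers run along; in the reference experiments fibers run along
y, so that is the default everywhere. Frames are 0-based and the time of
frame ``k`` is ``k * frame_interval`` minutes. Tracks may contain gaps
(missing frames); downstream metrics use actual time differences.

Supported on-disk formats
-------------------------
* Track table: UTF-8 CSV with header ``cell_id,frame,x_um,y_um[,phenotype]``.
* TrackMate XML: read-only subset (``Model/AllSpots`` + ``Model/AllTracks``);
  spatial units must be declared in microns (or convertible).
* Colony masks: multi-page TIFF, one page per frame, unsigned-integer labels
  (0 = background) or binary foreground.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile
from skimage.measure import label as _cc_label

from .errors import (
    EmptyInputError,
    FormatError,
    UnsupportedFeatureError,
    ValidationError,
)

__all__ = [
    "CellTrack",
    "TrackSet",
    "ColonyMaskStack",
    "read_tracks_table",
    "write_tracks_table",
    "read_trackmate_xml",
    "read_mask_stack",
    "write_mask_stack",
]

LEADER = "leader"
FOLLOWER = "follower"

#: case-insensitive synonyms accepted in phenotype columns; TGF-beta-induced
#: (mesenchymal) cells are leaders, uninduced epithelial cells are followers.
_PHENOTYPE_SYNONYMS = {
    "leader": LEADER,
    "tgf+": LEADER,
    "follower": FOLLOWER,
    "tgf-": FOLLOWER,
}

_MICRON_UNITS = {"µm", "um", "micron", "microns", "micrometer", "micrometre"}
_UNIT_TO_UM = {**{u: 1.0 for u in _MICRON_UNITS}, "nm": 1e-3, "mm": 1e3, "m": 1e6}


def normalize_phenotype(value) -> str | None:
    """Map a raw phenotype label to ``'leader'``/``'follower'`` or ``None``.

    Raises :class:`ValidationError` for unrecognized non-empty labels: failing
    loudly beats silently mislabeling a cell's phenotype.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().lower()
    if text in ("", "nan", "none"):
        return None
    try:
        return _PHENOTYPE_SYNONYMS[text]
    except KeyError:
        raise ValidationError(
            f"unrecognized phenotype label {value!r}; expected one of "
            f"{sorted(_PHENOTYPE_SYNONYMS)} (case-insensitive)"
        ) from None


@dataclass(frozen=True)
class CellTrack:
    """One cell's time-ordered positions with an optional phenotype label.

    Attributes
    ----------
    cell_id : str
        Opaque identifier, unique within a :class:`TrackSet`.
    frames : (n,) int array
        Strictly increasing 0-based frame indices; gaps are allowed.
    xy : (n, 2) float array
        Positions in µm, image convention.
    phenotype : {'leader', 'follower', None}
    """

    cell_id: str
    frames: np.ndarray
    xy: np.ndarray
    phenotype: str | None = None

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=np.int64)
        xy = np.asarray(self.xy, dtype=np.float64)
        if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] != frames.shape[0]:
            raise ValidationError(
                f"track {self.cell_id!r}: xy must be (n, 2) matching frames"
            )
        if frames.size and np.any(np.diff(frames) <= 0):
            raise ValidationError(
                f"track {self.cell_id!r}: frame indices must be strictly increasing"
            )
        if not np.all(np.isfinite(xy)):
            raise ValidationError(f"track {self.cell_id!r}: non-finite coordinates")
        if self.phenotype not in (None, LEADER, FOLLOWER):
            raise ValidationError(
                f"track {self.cell_id!r}: phenotype must be 'leader'/'follower'/None"
            )
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy", xy)
        frames.setflags(write=False)
        xy.setflags(write=False)

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def metric_eligible(self) -> bool:
        """True when the track has enough positions for any motion metric."""
        return len(self) >= 2

    def position_at(self, frame: int) -> np.ndarray | None:
        idx = np.searchsorted(self.frames, frame)
        if idx < len(self) and self.frames[idx] == frame:
            return self.xy[idx]
        return None


@dataclass(frozen=True)
class TrackSet:
    """All tracks of one colony/condition sharing a coordinate frame.

    ``condition`` is the leader percentage N of the colony (0-100), the
    experimental design variable; ``None`` when unknown.
    """

    tracks: tuple[CellTrack, ...]
    frame_interval: float  # minutes per frame
    fiber_axis: str = "y"
    condition: float | None = None
    n_dropped_rows: int = 0

    def __post_init__(self):
        object.__setattr__(self, "tracks", tuple(self.tracks))
        if not self.frame_interval > 0:
            raise ValidationError("frame_interval must be > 0")
        if self.fiber_axis not in ("x", "y"):
            raise ValidationError("fiber_axis must be 'x' or 'y'")
        if self.condition is not None and not 0.0 <= self.condition <= 100.0:
            raise ValidationError("condition N must lie in [0, 100]")
        ids = [t.cell_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate cell_id in TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def metric_eligible_tracks(self) -> tuple[CellTrack, ...]:
        return tuple(t for t in self.tracks if t.metric_eligible)

    @property
    def n_leaders(self) -> int:
        return sum(t.phenotype == LEADER for t in self.tracks)

    @property
    def n_followers(self) -> int:
        return sum(t.phenotype == FOLLOWER for t in self.tracks)

    @property
    def frame_range(self) -> tuple[int, int]:
        if not self.tracks:
            raise EmptyInputError("empty TrackSet has no frames")
        lo = min(int(t.frames[0]) for t in self.tracks)
        hi = max(int(t.frames[-1]) for t in self.tracks)
        return lo, hi

    def positions_at(self, frame: int) -> np.ndarray:
        """(m, 2) array of all cell positions recorded at ``frame``."""
        pts = [p for t in self.tracks if (p := t.position_at(frame)) is not None]
        return np.array(pts, dtype=float).reshape(-1, 2)

    def condition_from_phenotypes(self) -> float | None:
        """Leader percentage implied by the phenotype labels, or None."""
        labeled = [t for t in self.tracks if t.phenotype is not None]
        if not labeled:
            return None
        return 100.0 * sum(t.phenotype == LEADER for t in labeled) / len(labeled)

    def with_condition(self, condition: float) -> "TrackSet":
        return replace(self, condition=condition)


@dataclass(frozen=True)
class ColonyMaskStack:
    """Time-indexed colony label masks with physical pixel size.

    ``masks`` is a (t, h, w) integer array; 0 is background, k > 0 labels the
    k-th connected colony of that frame. Binary input is promoted to labels
    with 8-connected components.
    """

    masks: np.ndarray
    pixel_size: float  # µm per pixel
    frame_interval: float  # minutes

    def __post_init__(self):
        masks = np.asarray(self.masks)
        if masks.ndim != 3:
            raise ValidationError("masks must be a (t, h, w) stack")
        if not np.issubdtype(masks.dtype, np.integer):
            raise ValidationError("masks must have an integer dtype")
        if masks.min(initial=0) < 0:
            raise ValidationError("mask labels must be non-negative")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be > 0")
        if not self.frame_interval > 0:
            raise ValidationError("frame_interval must be > 0")
        object.__setattr__(self, "masks", masks)
        masks.setflags(write=False)

    def __len__(self) -> int:
        return int(self.masks.shape[0])

    def labels_at(self, frame: int) -> np.ndarray:
        page = self.masks[frame]
        return np.unique(page[page > 0])


# ---------------------------------------------------------------------------
# Track tables (CSV)
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("cell_id", "frame", "x_um", "y_um")


def read_tracks_table(
    path, frame_interval: float, fiber_axis: str = "y"
) -> TrackSet:
    """Read a CSV track table (TrackMate-spot-export compatible schema).

    Rows with missing coordinates are dropped and counted in
    ``TrackSet.n_dropped_rows``; tracks with a single position are retained
    (with a warning) but excluded from the metric-eligible set. The condition
    N is computed from the phenotype column when present.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"track table {path}: missing mandatory column {col!r}")
    n_raw = len(df)
    df = df.dropna(subset=["x_um", "y_um"])
    n_dropped = n_raw - len(df)
    if df.duplicated(subset=["cell_id", "frame"]).any():
        dup = df[df.duplicated(subset=["cell_id", "frame"], keep=False)].iloc[0]
        raise ValidationError(
            f"duplicate (cell_id, frame) pair: ({dup['cell_id']!r}, {int(dup['frame'])})"
        )
    has_phenotype = "phenotype" in df.columns
    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        phenotype = None
        if has_phenotype:
            labels = {normalize_phenotype(v) for v in grp["phenotype"]}
            labels.discard(None)
            if len(labels) > 1:
                raise ValidationError(
                    f"cell {cell_id!r} carries conflicting phenotype labels"
                )
            phenotype = labels.pop() if labels else None
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                frames=grp["frame"].to_numpy(dtype=np.int64),
                xy=grp[["x_um", "y_um"]].to_numpy(dtype=float),
                phenotype=phenotype,
            )
        )
    n_short = sum(not t.metric_eligible for t in tracks)
    if n_short:
        warnings.warn(
            f"{n_short} track(s) with <2 positions are not metric-eligible",
            stacklevel=2,
        )
    ts = TrackSet(
        tracks=tuple(tracks),
        frame_interval=frame_interval,
        fiber_axis=fiber_axis,
        n_dropped_rows=n_dropped,
    )
    cond = ts.condition_from_phenotypes()
    return ts.with_condition(cond) if cond is not None else ts


def write_tracks_table(ts: TrackSet, path) -> None:
    """Write a TrackSet as CSV; coordinates at 6 decimal places.

    ``read_tracks_table(write_tracks_table(ts))`` reproduces every coordinate
    to 6 decimals and every phenotype label exactly.
    """
    rows = []
    any_phenotype = any(t.phenotype is not None for t in ts.tracks)
    for t in ts.tracks:
        for k in range(len(t)):
            row = {
                "cell_id": t.cell_id,
                "frame": int(t.frames[k]),
                "x_um": t.xy[k, 0],
                "y_um": t.xy[k, 1],
            }
            if any_phenotype:
                row["phenotype"] = t.phenotype if t.phenotype is not None else ""
            rows.append(row)
    columns = list(_REQUIRED_COLUMNS) + (["phenotype"] if any_phenotype else [])
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# TrackMate XML (read-only subset)
# ---------------------------------------------------------------------------


def read_trackmate_xml(
    path,
    frame_interval: float | None = None,
    fiber_axis: str = "y",
    space_units_override: str | None = None,
) -> TrackSet:
    """Read tracks from the ``Model/AllSpots`` + ``Model/AllTracks`` subset
    of a TrackMate XML file.

    Coordinates are converted to µm via the file's ``spatialunits``
    declaration; a missing/unknown declaration is an error unless
    ``space_units_override`` supplies the units explicitly. Tracks that split
    or merge are rejected: linear track topology only.

    ``frame_interval`` (minutes) falls back to the file's
    ``Settings/ImageData@timeinterval`` when omitted.
    """
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not well-formed XML: {exc}") from exc
    model = root.find("Model") if root.tag != "Model" else root
    if model is None:
        raise FormatError(f"{path}: no <Model> element")

    units = model.get("spatialunits") or space_units_override
    if units is None:
        raise ValidationError(
            f"{path}: no spatialunits declaration; pass space_units_override"
        )
    factor = _UNIT_TO_UM.get(units.strip().lower())
    if factor is None:
        raise ValidationError(
            f"{path}: unsupported spatial units {units!r}; expected one of "
            f"{sorted(_UNIT_TO_UM)}"
        )

    if frame_interval is None:
        img = root.find("Settings/ImageData")
        if img is not None and img.get("timeinterval"):
            frame_interval = float(img.get("timeinterval"))
        else:
            raise ValidationError(
                f"{path}: no frame interval in file; pass frame_interval explicitly"
            )

    spots: dict[str, tuple[int, float, float]] = {}
    for spot in model.iter("Spot"):
        sid = spot.get("ID")
        frame_attr = spot.get("FRAME")
        if frame_attr is None:
            raise FormatError(f"{path}: Spot {sid!r} lacks FRAME attribute")
        spots[sid] = (
            int(float(frame_attr)),
            float(spot.get("POSITION_X")) * factor,
            float(spot.get("POSITION_Y")) * factor,
        )

    tracks = []
    all_tracks = model.find("AllTracks")
    if all_tracks is None:
        raise FormatError(f"{path}: no <AllTracks> element")
    for trk in all_tracks.iter("Track"):
        track_id = trk.get("TRACK_ID", trk.get("name", "?"))
        sources: dict[str, str] = {}
        members: set[str] = set()
        seen_targets: set[str] = set()
        for edge in trk.iter("Edge"):
            src, dst = edge.get("SPOT_SOURCE_ID"), edge.get("SPOT_TARGET_ID")
            if src in sources or dst in seen_targets:
                raise UnsupportedFeatureError(
                    f"{path}: track {track_id} splits or merges; branching "
                    "tracks are not supported"
                )
            sources[src] = dst
            seen_targets.add(dst)
            members.update((src, dst))
        missing = members - spots.keys()
        if missing:
            raise FormatError(
                f"{path}: track {track_id} references unknown spot(s) {sorted(missing)}"
            )
        ordered = sorted(members, key=lambda s: spots[s][0])
        frames = np.array([spots[s][0] for s in ordered], dtype=np.int64)
        xy = np.array([[spots[s][1], spots[s][2]] for s in ordered], dtype=float)
        tracks.append(CellTrack(cell_id=str(track_id), frames=frames, xy=xy))
    return TrackSet(tracks=tuple(tracks), frame_interval=frame_interval, fiber_axis=fiber_axis)


# ---------------------------------------------------------------------------
# Mask stacks (multi-page TIFF)
# ---------------------------------------------------------------------------


def read_mask_stack(path, pixel_size: float, frame_interval: float) -> ColonyMaskStack:
    """Read a multi-page TIFF of colony masks.

    Binary pages (values in {0, 1} or boolean) are promoted to label images
    via 8-connected component labeling; integer pages with larger values are
    taken as labels as-is. Float-valued images are rejected: thresholding
    belongs upstream.
    """
    arr = tifffile.imread(path)
    if np.issubdtype(arr.dtype, np.floating):
        raise ValidationError(
            f"{path}: float-valued image; threshold/binarize upstream before reading"
        )
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise ValidationError(f"{path}: expected 2-D pages, got shape {arr.shape}")
    if arr.dtype == bool or arr.max(initial=0) <= 1:
        pages = [_cc_label(page > 0, connectivity=2) for page in arr]
        arr = np.stack(pages).astype(np.int32)
    else:
        arr = arr.astype(np.int32)
    return ColonyMaskStack(masks=arr, pixel_size=pixel_size, frame_interval=frame_interval)


def write_mask_stack(stack: ColonyMaskStack, path) -> None:
    """Write a mask stack as an unsigned-integer multi-page TIFF."""
    data = stack.masks
    if data.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValidationError("label values exceed uint16 range")
    tifffile.imwrite(path, data.astype(np.uint16))
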