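"""Shared fixtures: synthetic tracks, rasterized shapes, TrackMate-style XML.

All fixtures are generated programmatically; nothing is read from disk except
files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from colonytrack.io import CellTrack, TrackSet


def make_track(points, cell_id="c0", phenotype=None, frames=None):
    """CellTrack from a list of (x, y) pairs, frames 0..n-1 unless given."""
    xy = np.asarray(points, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return CellTrack(cell_id=cell_id, frames=np.asarray(frames), xy=xy, phenotype=phenotype)


def make_trackset(tracks, frame_interval=15.0, fiber_axis="y", condition=None):
    return TrackSet(
        tracks=tuple(tracks),
        frame_interval=frame_interval,
        fiber_axis=fiber_axis,
        condition=condition,
    )


def random_track(rng, n_steps=20, step=2.0, cell_id="r0", phenotype=None):
    angles = rng.uniform(0, 2 * np.pi, size=n_steps)
    steps = step * np.column_stack([np.cos(angles), np.sin(angles)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) + rng.normal(0, 5, size=2)
    return make_track(xy, cell_id=cell_id, phenotype=phenotype)


def rasterize_disk(radius_px, pad=4, label=1):
    """Binary label image of a centered disk (pixel-center rasterization)."""
    size = 2 * (radius_px + pad) + 1
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    return (label * ((xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2)).astype(np.int32)


def rasterize_ellipse(a_px, b_px, angle_deg=0.0, pad=4, label=1):
    """Binary label image of a centered rotated ellipse with semi-axes a, b."""
    size = 2 * (int(max(a_px, b_px)) + pad) + 1
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    x, y = xx - c, yy - c
    t = np.deg2rad(angle_deg)
    u = x * np.cos(t) + y * np.sin(t)
    v = -x * np.sin(t) + y * np.cos(t)
    return (label * ((u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0)).astype(np.int32)


def trackmate_xml(tracks, spatialunits="micron", timeinterval=None, scale=1.0):
    """Minimal TrackMate-style XML for a list of CellTracks.

    ``scale`` divides the stored coordinates so that unit conversion can be
    exercised (e.g. store mm with scale=1000).
    """
    spot_lines, sif = [], {}
    track_lines = []
    sid = 0
    for k, t in enumerate(tracks):
        ids = []
        for i in range(len(t)):
            fr = int(t.frames[i])
            sif.setdefault(fr, []).append(
                f'<Spot ID="{sid}" FRAME="{fr}" '
                f'POSITION_X="{float(t.xy[i, 0]) / scale!r}" '
                f'POSITION_Y="{float(t.xy[i, 1]) / scale!r}" />'
            )
            ids.append(sid)
            sid += 1
        edges = "".join(
            f'<Edge SPOT_SOURCE_ID="{a}" SPOT_TARGET_ID="{b}" />'
            for a, b in zip(ids[:-1], ids[1:])
        )
        track_lines.append(f'<Track TRACK_ID="{k}" name="Track_{k}">{edges}</Track>')
    frames_xml = "".join(
        f'<SpotsInFrame frame="{fr}">' + "".join(lines) + "</SpotsInFrame>"
        for fr, lines in sorted(sif.items())
    )
    units = f' spatialunits="{spatialunits}"' if spatialunits else ""
    settings = (
        f'<Settings><ImageData timeinterval="{timeinterval}" /></Settings>'
        if timeinterval is not None
        else ""
    )
    return (
        "<TrackMate>"
        f"<Model{units}>"
        f"<AllSpots>{frames_xml}</AllSpots>"
        f"<AllTracks>{''.join(track_lines)}</AllTracks>"
        "</Model>"
        f"{settings}"
        "</TrackMate>"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
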