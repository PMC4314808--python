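"""Greedy nearest-neighbour linking of detections into tracks.

Detections are matched frame-to-frame in ascending distance order,
rejecting pairs farther than ``max_disp * (gap + 1)``; a track not
extended for more than ``max_gap`` frames is closed.  Ties in distance
break on the lexicographically lowest (frame, label) identifiers so
the result is invariant to the order detections arrive in.  Greedy
matching is adequate in the sparse-cell regime typical of live-imaged
lymphocytes and is validated against an exhaustive optimal-assignment
oracle on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import Track, TrackSet

__all__ = ["LinkingConfig", "link_detections", "heading_at", "track_headings"]


@dataclass(frozen=True)
class LinkingConfig:
    """Linking parameters.

    max_disp : maximum displacement in um per frame of gap (+1).
    max_gap : number of consecutive missing frames a track may bridge.
    min_track_len : minimum number of detections a reported track needs.
    """

    max_disp: float = 15.0
    max_gap: int = 0
    min_track_len: int = 2

    def __post_init__(self) -> None:
        if self.max_disp <= 0:
            raise ValueError(f"max_disp must be > 0, got {self.max_disp}")
        if self.max_gap < 0:
            raise ValueError(f"max_gap must be >= 0, got {self.max_gap}")
        if self.min_track_len < 2:
            raise ValueError(f"min_track_len must be >= 2, got {self.min_track_len}")


def link_detections(
    detections: pd.DataFrame,
    cfg: LinkingConfig = LinkingConfig(),
    dt: float = 30.0,
    pixel_size: float = 1.0,
    source_point: tuple[float, float] | None = None,
) -> TrackSet:
    """Link a detection table (see :mod:`pcpmig.detect`) into a TrackSet.

    Empty input yields an empty TrackSet.  Each detection joins at most
    one track; tracks shorter than ``cfg.min_track_len`` are dropped.
    """
    if len(detections) == 0:
        return TrackSet(tracks=[], dt=dt, pixel_size=pixel_size, source_point=source_point)

    # canonical order makes the greedy pass permutation-invariant
    det = detections.sort_values(["frame", "label"]).reset_index(drop=True)
    frames = sorted(det["frame"].unique())

    # active track state: list of dicts with detection row indices
    active: list[dict] = []
    finished: list[dict] = []

    by_frame = {f: det.index[det["frame"] == f].to_numpy() for f in frames}

    for f in frames:
        idxs = by_frame[f]
        # candidate (distance, track_key, det_key) pairs
        candidates = []
        for ti, tr in enumerate(active):
            gap = f - tr["last_frame"] - 1
            if gap > cfg.max_gap or gap < 0:
                continue
            limit = cfg.max_disp * (gap + 1)
            lx, ly = tr["last_x"], tr["last_y"]
            for di in idxs:
                d = np.hypot(det.at[di, "x_um"] - lx, det.at[di, "y_um"] - ly)
                if d <= limit:
                    candidates.append(
                        (d, tr["last_key"], (f, int(det.at[di, "label"])), ti, di)
                    )
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, _tk, _dk, ti, di in candidates:
            if ti in used_tracks or di in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(di)
            tr = active[ti]
            tr["rows"].append(di)
            tr["last_frame"] = f
            tr["last_x"] = det.at[di, "x_um"]
            tr["last_y"] = det.at[di, "y_um"]
            tr["last_key"] = (f, int(det.at[di, "label"]))
        # unmatched detections start new tracks
        for di in idxs:
            if di not in used_dets:
                active.append(
                    {
                        "rows": [di],
                        "last_frame": f,
                        "last_x": det.at[di, "x_um"],
                        "last_y": det.at[di, "y_um"],
                        "last_key": (f, int(det.at[di, "label"])),
                    }
                )
        # retire tracks that can no longer be extended
        still = []
        for tr in active:
            if f - tr["last_frame"] > cfg.max_gap:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
    finished.extend(active)

    # stable track ids in order of first (frame, label)
    finished.sort(key=lambda tr: (int(det.at[tr["rows"][0], "frame"]), int(det.at[tr["rows"][0], "label"])))
    tracks = []
    cid = 0
    for tr in finished:
        if len(tr["rows"]) < cfg.min_track_len:
            continue
        rows = det.loc[tr["rows"]]
        tracks.append(
            Track(
                cell_id=cid,
                t=rows["frame"].to_numpy(dtype=float) * dt,
                x=rows["x_um"].to_numpy(dtype=float),
                y=rows["y_um"].to_numpy(dtype=float),
                frames=rows["frame"].to_numpy(dtype=int),
            )
        )
        cid += 1
    return TrackSet(tracks=tracks, dt=dt, pixel_size=pixel_size, source_point=source_point)


def heading_at(track: Track, index: int, min_step: float = 1.0):
    """Heading (unit vector) of ``track`` at sample ``index``.

    The heading is the normalised displacement from the nearest
    preceding sample at least ``min_step`` um away — sub-pixel jitter
    must not flip the leading/trailing assignment.  If no such sample
    exists, the last previously valid heading is reused; if the cell
    never moved that far, returns None ("undefined").
    """
    if index < 0 or index >= len(track):
        raise IndexError(f"sample {index} outside track {track.cell_id}")
    return track_headings(track, min_step)[index]


def track_headings(track: Track, min_step: float = 1.0) -> list:
    """Per-sample headings for a whole track (None where undefined)."""
    n = len(track)
    out: list = [None] * n
    last_valid = None
    for i in range(n):
        found = None
        for j in range(i - 1, -1, -1):
            dx = track.x[i] - track.x[j]
            dy = track.y[i] - track.y[j]
            d = np.hypot(dx, dy)
            if d >= min_step:
                found = np.array([dx / d, dy / d])
                break
        if found is not None:
            last_valid = found
        out[i] = last_valid
    return out
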