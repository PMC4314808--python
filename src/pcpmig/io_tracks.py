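"""CSV round-trip for track tables and ground truth.

Tracks CSV dialect: header ``cell_id,frame,t_s,x_um,y_um``, UTF-8,
"." decimal.  Reading canonicalises row order (per-cell time sort) and
rejects malformed input with the offending line numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth
from .tracks import Track, TrackSet

__all__ = ["write_tracks", "read_tracks", "write_ground_truth"]

TRACK_COLUMNS = ["cell_id", "frame", "t_s", "x_um", "y_um"]


def write_tracks(track_set: TrackSet, path) -> Path:
    """Write a TrackSet to the tracks CSV dialect."""
    path = Path(path)
    rows = []
    for tr in track_set:
        frames = (
            tr.frames
            if tr.frames is not None
            else np.round(tr.t / track_set.dt).astype(int)
        )
        for i in range(len(tr)):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "frame": int(frames[i]),
                    "t_s": tr.t[i],
                    "x_um": tr.x[i],
                    "y_um": tr.y[i],
                }
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False, float_format="%.6f")
    return path


def read_tracks(
    path,
    dt: float = 30.0,
    pixel_size: float = 1.0,
    source_point: tuple[float, float] | None = None,
) -> TrackSet:
    """Read a tracks CSV written by :func:`write_tracks`.

    Rows may arrive in any order (they are sorted per cell by time);
    duplicate (cell_id, frame) rows and non-monotone timestamps are
    rejected with the 1-based line numbers of the offenders.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    # line number in file = dataframe index + 2 (header is line 1)
    df = df.assign(_line=df.index + 2)
    dupes = df[df.duplicated(subset=["cell_id", "frame"], keep=False)]
    if len(dupes):
        pairs = dupes.groupby(["cell_id", "frame"])["_line"].apply(list)
        first = pairs.iloc[0]
        key = pairs.index[0]
        raise ValueError(
            f"{path}: duplicate (cell_id, frame) = {key} at lines {sorted(first)}"
        )
    tracks = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_s")
        bad = grp["_line"].to_numpy()[1:][np.diff(grp["t_s"].to_numpy()) <= 0]
        if bad.size:
            raise ValueError(
                f"{path}: non-monotone timestamps for cell {cid} at line(s) {bad.tolist()}"
            )
        tracks.append(
            Track(
                cell_id=int(cid),
                t=grp["t_s"].to_numpy(float),
                x=grp["x_um"].to_numpy(float),
                y=grp["y_um"].to_numpy(float),
                frames=grp["frame"].to_numpy(int),
            )
        )
    return TrackSet(tracks=tracks, dt=dt, pixel_size=pixel_size, source_point=source_point)


def write_ground_truth(truth: GroundTruth, path) -> Path:
    """Write the per-frame ground-truth table (CSV)."""
    path = Path(path)
    cols = ["cell_id", "frame", "heading_deg", "polarity_axis_deg", "polarity_amplitude"]
    truth.frames[cols].to_csv(path, index=False, float_format="%.6f")
    return path
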