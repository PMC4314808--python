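"""Track containers: time-ordered positions of single cells in physical units."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Track", "TrackSet"]


@dataclass
class Track:
    """Time-ordered path of one cell.

    ``t`` is in seconds, ``x``/``y`` in micrometres; all three arrays
    share length >= 1 and timestamps are strictly increasing.
    """

    cell_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frames: np.ndarray | None = None  # original frame indices, if known

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError(f"track {self.cell_id}: t, x, y lengths differ")
        if len(self.t) < 1:
            raise ValueError(f"track {self.cell_id}: needs >= 1 sample")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.cell_id}: timestamps must strictly increase")
        if not (
            np.all(np.isfinite(self.t))
            and np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
        ):
            raise ValueError(f"track {self.cell_id}: coordinates must be finite")
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=int)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in um."""
        return np.column_stack([self.x, self.y])


@dataclass
class TrackSet:
    """A collection of tracks acquired at a common frame interval.

    Attributes
    ----------
    tracks : list of Track
    dt : float
        Frame interval in seconds (> 0).
    pixel_size : float
        Pixel size in um/px (> 0); carried so image-derived tracks keep
        their provenance.
    source_point : (float, float) or None
        Position of the chemokine source in um, if a gradient exists.
    """

    tracks: list[Track] = field(default_factory=list)
    dt: float = 30.0
    pixel_size: float = 1.0
    source_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)
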