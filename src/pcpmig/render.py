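"""Rendering of synthetic two-channel time-lapse stacks.

Channel layout follows the acquisition the simulator emulates: a
membrane polarity marker (e.g. VANGL2-EGFP) and a whole-cell
cytoplasmic tracker dye.  The tracker channel renders each cell as a
filled disc; the polarity channel renders a perimeter ring whose
intensity at perimeter angle phi is

    base_intensity * (1 + A * cos(phi - phi_peak))

with phi_peak the polarity axis (opposite the heading for
trailing-edge-enriched markers).  Averaging the modulation over the
trailing and leading half-rings gives mean intensities proportional to
1 + 2A/pi and 1 - 2A/pi, so the ideal trailing/leading ratio is
(1 + 2A/pi) / (1 - 2A/pi) — the closed form the polarity module is
validated against.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .simulate import GroundTruth
from .tracks import TrackSet

__all__ = ["FrameStack", "NoiseModel", "render_frames", "write_stack", "read_stack"]

CHANNEL_NAMES = ("polarity_marker", "cell_tracker")


@dataclass
class FrameStack:
    """A two-channel time-lapse image volume.

    ``data`` is a (T, C, H, W) non-negative float array in arbitrary
    intensity units; ``pixel_size`` in um/px, ``dt`` in seconds.
    """

    data: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    pixel_size: float = 1.0
    dt: float = 30.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (T, C, H, W), got shape {self.data.shape}")
        t, c = self.data.shape[:2]
        if t < 1 or c not in (1, 2):
            raise ValueError(f"need T >= 1 and C in {{1, 2}}, got T={t}, C={c}")
        if np.any(self.data < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """(T, H, W) view of one channel by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[:, idx]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian read noise plus optional Poisson shot noise."""

    gaussian_sd: float = 0.0
    poisson_scaling: bool = False


def render_frames(
    track_set: TrackSet,
    truth: GroundTruth,
    cell_radius: float = 8.0,
    base_intensity: float = 1000.0,
    noise_model: NoiseModel = NoiseModel(),
    image_shape: tuple[int, int] = (200, 200),
    seed: int = 0,
    ring_width: float | None = None,
) -> FrameStack:
    """Render ground-truth cell states into a two-channel FrameStack.

    Parameters
    ----------
    track_set
        Carries pixel size and frame interval; positions come from
        ``truth`` so rendering is exact even if tracks were filtered.
    cell_radius : float
        Cell radius in um; must map to >= 2 px.
    noise_model
        Applied to the noise-free image, independently of the
        trajectory seed; result is clipped at 0.
    image_shape
        (H, W) in pixels.  Cells outside the field are clipped
        silently.
    ring_width : float or None
        Radial thickness of the polarity ring in um; defaults to a
        quarter of the radius (>= 1 px).
    """
    px = track_set.pixel_size
    if cell_radius <= 0 or cell_radius / px < 2.0:
        raise ValueError(
            f"cell_radius {cell_radius} um is below 2 px at pixel_size {px} um/px; "
            "detection would be meaningless"
        )
    if ring_width is None:
        ring_width = max(cell_radius / 4.0, px)

    h, w = image_shape
    n_frames = int(truth.frames["frame"].max()) + 1
    data = np.zeros((n_frames, 2, h, w))
    pol = data[:, CHANNEL_NAMES.index("polarity_marker")]
    trk = data[:, CHANNEL_NAMES.index("cell_tracker")]

    r_px = cell_radius / px
    pad = int(np.ceil(r_px)) + 1

    for row in truth.frames.itertuples(index=False):
        f = int(row.frame)
        cx, cy = row.x_um / px, row.y_um / px  # pixel coords, 0-based centres
        x0, x1 = max(0, int(np.floor(cx)) - pad), min(w, int(np.ceil(cx)) + pad + 1)
        y0, y1 = max(0, int(np.floor(cy)) - pad), min(h, int(np.ceil(cy)) + pad + 1)
        if x0 >= x1 or y0 >= y1:
            continue  # fully out of field
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        dist = np.hypot(dx, dy) * px  # um
        disc = dist <= cell_radius
        trk[f, y0:y1, x0:x1][disc] += base_intensity
        ring = disc & (dist >= cell_radius - ring_width)
        amp = row.polarity_amplitude
        phi_peak = np.radians(row.polarity_axis_deg)
        phi = np.arctan2(dy, dx)
        modulation = 1.0 + amp * np.cos(phi - phi_peak)
        pol[f, y0:y1, x0:x1][ring] += base_intensity * modulation[ring]

    if noise_model.poisson_scaling or noise_model.gaussian_sd > 0:
        noise_rng = np.random.default_rng(seed)
        if noise_model.poisson_scaling:
            data = noise_rng.poisson(data).astype(float)
        if noise_model.gaussian_sd > 0:
            data = data + noise_rng.normal(0.0, noise_model.gaussian_sd, data.shape)
        data = np.clip(data, 0.0, None)

    return FrameStack(
        data=data, channel_names=CHANNEL_NAMES, pixel_size=px, dt=track_set.dt
    )


def write_stack(stack: FrameStack, directory, prefix: str = "stack") -> list[Path]:
    """Write one 16-bit multi-page TIFF per channel plus a sidecar.

    The sidecar ``<prefix>.meta.txt`` holds pixel_size_um and dt_s as
    key=value lines.  Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, name in enumerate(stack.channel_names):
        path = directory / f"{prefix}_{name}.tif"
        arr = np.clip(np.round(stack.data[:, i]), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, arr, photometric="minisblack")
        paths.append(path)
    meta = directory / f"{prefix}.meta.txt"
    meta.write_text(
        f"pixel_size_um={stack.pixel_size}\n"
        f"dt_s={stack.dt}\n"
        f"channels={','.join(stack.channel_names)}\n"
    )
    paths.append(meta)
    return paths


def read_stack(directory, prefix: str = "stack") -> FrameStack:
    """Read a FrameStack written by :func:`write_stack`."""
    directory = Path(directory)
    meta = {}
    for line in (directory / f"{prefix}.meta.txt").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    names = tuple(meta["channels"].split(","))
    channels = []
    for name in names:
        arr = tifffile.imread(directory / f"{prefix}_{name}.tif").astype(float)
        if arr.ndim == 2:  # single-page stacks read back as (H, W)
            arr = arr[None]
        channels.append(arr)
    data = np.stack(channels, axis=1)
    return FrameStack(
        data=data,
        channel_names=names,
        pixel_size=float(meta["pixel_size_um"]),
        dt=float(meta["dt_s"]),
    )
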