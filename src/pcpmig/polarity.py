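"""Front-rear polarity quantification: R = I_trailing / I_leading.

A migrating lymphocyte is split into its leading and trailing halves
by the line through the cell centroid perpendicular to the direction
of motion; the polarity ratio is the mean marker intensity in the
trailing half divided by the leading half.  R = 1 indicates a
symmetric marker distribution; trailing-edge-enriched PCP proteins
such as VANGL2 give R > 1, leading-edge-enriched ones (DVL3,
beta-arrestin) give R < 1.

The two half-cell regions operationalise "two regions of interest of
the same size": they are disjoint, tile the mask, and for symmetric
masks differ in area by at most one pixel (pixels exactly on the
split line alternate deterministically between the halves).

The ratio is scale-invariant (multiplying the image by c > 0 leaves it
unchanged) but NOT offset-invariant; constant-background subtraction,
estimated from the darkest pixels outside all cell masks, is therefore
applied before the ratio when enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label

from .link import track_headings
from .render import FrameStack
from .tracks import Track

__all__ = [
    "PolarityMeasurement",
    "PolarityConfig",
    "split_cell",
    "polarity_ratio",
    "measure_track_polarity",
    "asymmetry_dose_curve",
    "estimate_background",
]


@dataclass(frozen=True)
class PolarityMeasurement:
    """Leading/trailing intensities and their ratio for one cell, one frame."""

    cell_id: int
    frame: int
    I_leading: float
    I_trailing: float
    ratio: float  # NaN when invalid
    heading_deg: float
    valid: bool


@dataclass(frozen=True)
class PolarityConfig:
    """Options for track-level polarity measurement."""

    channel: str = "polarity_marker"
    mask_channel: str = "cell_tracker"
    threshold: "str | float" = "otsu"
    min_step: float = 1.0  # um; heading definition cutoff
    ring_only: bool = False  # measure on the membrane ring instead of the full mask
    ring_width: float = 2.0  # um, used when ring_only
    subtract_background: bool = False
    border_margin: int = 1  # px; cells touching the border are invalid


def split_cell(
    mask: np.ndarray, centroid_px: tuple[float, float], heading: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split a binary cell mask into (leading, trailing) boolean masks.

    ``centroid_px`` is (x, y) in pixel coordinates; ``heading`` a unit
    vector.  Pixels with positive projection of (pixel - centroid)
    onto the heading are leading, negative trailing; zero-projection
    pixels alternate (in row-major order) onto whichever half is
    currently smaller, equalising areas deterministically.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("split_cell: empty mask")
    heading = np.asarray(heading, dtype=float)
    norm = np.hypot(*heading)
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("split_cell: heading must be a nonzero finite vector")
    hx, hy = heading / norm
    cx, cy = centroid_px

    yy, xx = np.nonzero(mask)
    proj = (xx - cx) * hx + (yy - cy) * hy
    leading = np.zeros_like(mask)
    trailing = np.zeros_like(mask)
    leading[yy[proj > 0], xx[proj > 0]] = True
    trailing[yy[proj < 0], xx[proj < 0]] = True

    zero_idx = np.nonzero(proj == 0)[0]
    n_lead = int(leading.sum())
    n_trail = int(trailing.sum())
    for k in zero_idx:  # row-major order of np.nonzero: deterministic
        if n_lead <= n_trail:
            leading[yy[k], xx[k]] = True
            n_lead += 1
        else:
            trailing[yy[k], xx[k]] = True
            n_trail += 1
    return leading, trailing


def polarity_ratio(
    intensity_image: np.ndarray,
    regions: tuple[np.ndarray, np.ndarray],
    cell_id: int = -1,
    frame: int = -1,
    heading_deg: float = float("nan"),
) -> PolarityMeasurement:
    """Mean-intensity ratio trailing/leading over the two half-masks.

    A non-positive leading mean marks the measurement invalid (the
    ratio is undefined, never +/-inf).
    """
    leading, trailing = regions
    img = np.asarray(intensity_image, dtype=float)
    i_lead = float(img[leading].mean()) if leading.any() else 0.0
    i_trail = float(img[trailing].mean()) if trailing.any() else 0.0
    valid = i_lead > 0
    ratio = i_trail / i_lead if valid else float("nan")
    return PolarityMeasurement(
        cell_id=cell_id,
        frame=frame,
        I_leading=i_lead,
        I_trailing=i_trail,
        ratio=ratio,
        heading_deg=heading_deg,
        valid=valid,
    )


def estimate_background(image: np.ndarray, all_masks: np.ndarray) -> float:
    """Constant background: mean of the darkest 5% of pixels outside masks."""
    outside = np.asarray(image, float)[~np.asarray(all_masks, bool)]
    if outside.size == 0:
        return 0.0
    k = max(1, int(0.05 * outside.size))
    return float(np.partition(outside, k - 1)[:k].mean())


def _cell_mask_at(frame_img, pos_px, threshold):
    """Connected component of the thresholded frame containing pos_px."""
    from skimage.filters import threshold_otsu

    if np.ptp(frame_img) == 0:
        return None, None
    thr = threshold_otsu(frame_img) if threshold == "otsu" else float(threshold)
    binary = frame_img > thr
    if not binary.any():
        return None, None
    labels = sk_label(binary, connectivity=2)
    x, y = pos_px
    xi = int(np.clip(round(x), 0, frame_img.shape[1] - 1))
    yi = int(np.clip(round(y), 0, frame_img.shape[0] - 1))
    lab = labels[yi, xi]
    if lab == 0:
        # fall back to the component nearest the expected position
        yy, xx = np.nonzero(binary)
        d2 = (xx - x) ** 2 + (yy - y) ** 2
        lab = labels[yy[np.argmin(d2)], xx[np.argmin(d2)]]
    return labels == lab, binary


def measure_track_polarity(
    stack: FrameStack,
    track: Track,
    headings: list | None = None,
    cfg: PolarityConfig = PolarityConfig(),
) -> tuple[list[PolarityMeasurement], float]:
    """Per-frame polarity measurements along a track, plus the cell summary.

    ``headings`` may supply one unit vector (or None) per track sample
    — e.g. ground-truth axes, or pre-arrest headings for drug-arrested
    cells; by default headings are derived from the track itself with
    the last valid heading reused on frames without sufficient motion.

    Returns (measurements, summary) where summary is the median ratio
    over valid frames (NaN if no frame is valid).
    """
    if headings is None:
        headings = track_headings(track, cfg.min_step)
    if len(headings) != len(track):
        raise ValueError("headings must align with track samples")

    px = stack.pixel_size
    marker = stack.channel(cfg.channel)
    mask_imgs = stack.channel(cfg.mask_channel)
    frames = track.frames if track.frames is not None else np.round(track.t / stack.dt).astype(int)

    out: list[PolarityMeasurement] = []
    h_img, w_img = marker.shape[1:]
    for i, f in enumerate(frames):
        f = int(f)
        if f < 0 or f >= stack.n_frames:
            continue
        heading = headings[i]
        if heading is None:
            continue  # undefined heading: measurement skipped
        pos_px = (track.x[i] / px, track.y[i] / px)
        mask, binary = _cell_mask_at(mask_imgs[f], pos_px, cfg.threshold)
        if mask is None:
            continue
        yy, xx = np.nonzero(mask)
        m = cfg.border_margin
        if (
            yy.min() < m
            or xx.min() < m
            or yy.max() >= h_img - m
            or xx.max() >= w_img - m
        ):
            # truncated halves bias the ratio
            out.append(
                PolarityMeasurement(
                    cell_id=track.cell_id, frame=f, I_leading=np.nan,
                    I_trailing=np.nan, ratio=np.nan,
                    heading_deg=float(np.degrees(np.arctan2(heading[1], heading[0]))),
                    valid=False,
                )
            )
            continue
        centroid_px = (xx.mean(), yy.mean())
        if cfg.ring_only:
            dist_um = np.hypot(xx - centroid_px[0], yy - centroid_px[1]) * px
            r_max = dist_um.max()
            keep = dist_um >= r_max - cfg.ring_width
            ring = np.zeros_like(mask)
            ring[yy[keep], xx[keep]] = True
            region_mask = ring
        else:
            region_mask = mask
        img = marker[f]
        if cfg.subtract_background:
            img = img - estimate_background(img, binary)
            img = np.clip(img, 0.0, None)
        leading, trailing = split_cell(region_mask, centroid_px, heading)
        meas = polarity_ratio(
            img, (leading, trailing), cell_id=track.cell_id, frame=f,
            heading_deg=float(np.degrees(np.arctan2(heading[1], heading[0]))),
        )
        out.append(meas)

    valid_ratios = [m.ratio for m in out if m.valid]
    summary = float(np.median(valid_ratios)) if valid_ratios else float("nan")
    return out, summary


def measurements_table(measurements: list[PolarityMeasurement]) -> pd.DataFrame:
    """Flatten measurements to the polarity CSV schema."""
    return pd.DataFrame(
        [
            {
                "cell_id": m.cell_id,
                "frame": m.frame,
                "I_leading": m.I_leading,
                "I_trailing": m.I_trailing,
                "ratio": m.ratio,
                "heading_deg": m.heading_deg,
                "valid": int(m.valid),
            }
            for m in measurements
        ],
        columns=["cell_id", "frame", "I_leading", "I_trailing", "ratio", "heading_deg", "valid"],
    )


def asymmetry_dose_curve(
    stacks: dict[float, tuple[FrameStack, list[Track]]],
    cfg: PolarityConfig = PolarityConfig(),
) -> pd.DataFrame:
    """Mean polarity ratio per inhibitor dose, ready for dose-response fitting.

    ``stacks`` maps dose (uM) to (FrameStack, tracks).  Needs >= 4
    doses; a dose contributing zero valid cells is an error naming the
    dose.  Returns a DataFrame with dose_um, response (mean per-cell
    ratio) and n_cells.
    """
    if len(stacks) < 4:
        raise ValueError(f"asymmetry dose curve needs >= 4 doses, got {len(stacks)}")
    rows = []
    for dose in sorted(stacks):
        stack, tracks = stacks[dose]
        summaries = []
        for tr in tracks:
            _, s = measure_track_polarity(stack, tr, cfg=cfg)
            if np.isfinite(s):
                summaries.append(s)
        if not summaries:
            raise ValueError(f"dose {dose} uM produced no valid polarity measurements")
        rows.append(
            {"dose_um": dose, "response": float(np.mean(summaries)), "n_cells": len(summaries)}
        )
    return pd.DataFrame(rows)
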