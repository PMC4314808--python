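"""Per-frame cell detection on the tracker channel.

Replaces manual cell selection in commercial tracking software with a
parameter-free pipeline: global threshold (Otsu by default), 8-connected
components, minimum-area filter, intensity-weighted centroids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .render import FrameStack

__all__ = ["detect_cells", "DETECTION_COLUMNS"]

DETECTION_COLUMNS = ["frame", "label", "x_um", "y_um", "area_um2", "mean_ch0", "mean_ch1"]


def detect_cells(
    stack: FrameStack,
    channel: str = "cell_tracker",
    threshold="otsu",
    min_area: float = 20.0,
) -> pd.DataFrame:
    """Detect cells in every frame of ``stack``.

    Parameters
    ----------
    channel
        Channel to threshold (the tracker dye fills the whole cell).
    threshold
        Absolute intensity threshold, or ``"otsu"`` for a per-frame
        Otsu threshold.
    min_area : float
        Minimum component area in um^2 (> 0); smaller components are
        discarded.

    Returns
    -------
    DataFrame with columns frame, label, x_um, y_um, area_um2,
    mean_ch0, mean_ch1.  All-zero frames simply yield no rows.
    """
    if min_area <= 0:
        raise ValueError(f"min_area must be > 0, got {min_area}")
    imgs = stack.channel(channel)  # validates the channel name
    px = stack.pixel_size
    px_area = px * px
    rows = []
    for f in range(stack.n_frames):
        img = imgs[f]
        if img.max() <= 0 or np.ptp(img) == 0:
            continue
        thr = threshold_otsu(img) if threshold == "otsu" else float(threshold)
        mask = img > thr
        if not mask.any():
            continue
        labels = label(mask, connectivity=2)
        for rp in regionprops(labels, intensity_image=img):
            area = rp.area * px_area
            if area < min_area:
                continue
            cy, cx = rp.centroid_weighted
            row = {
                "frame": f,
                "label": rp.label,
                "x_um": cx * px,
                "y_um": cy * px,
                "area_um2": area,
            }
            for c in range(stack.data.shape[1]):
                ch_img = stack.data[f, c]
                row[f"mean_ch{c}"] = float(ch_img[rp.slice][rp.image].mean())
            if stack.data.shape[1] == 1:
                row["mean_ch1"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS).astype(
        {"frame": int, "label": int}
    ) if rows else pd.DataFrame(columns=DETECTION_COLUMNS)
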