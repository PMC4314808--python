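"""Per-track migration statistics, group comparison and dose-response fit.

The four endpoint statistics of a tracked cell are:

* track length — total path length, sum of consecutive step distances;
* displacement length — straight-line distance from start to end;
* maximum speed — the largest single-step speed (a step bridging a
  detection gap divides by the full elapsed time, so gaps never
  inflate the maximum);
* straightness — displacement / track length, 1 for a perfectly
  straight path, undefined (NaN) for a cell that never moved.

The transwell migration index is the chemokine-driven migrated-cell
count divided by the control-medium count.  Inhibitor dose-response
data are fitted with the four-parameter logistic (variable-slope)
model on log-dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tracks import Track, TrackSet

__all__ = [
    "MigrationMetrics",
    "DoseResponseFit",
    "track_metrics",
    "summarize",
    "migration_index",
    "kruskal_wallis",
    "four_param_logistic",
    "fit_dose_response",
]

METRIC_NAMES = ("track_length_um", "displacement_um", "max_speed_um_min", "straightness")


@dataclass(frozen=True)
class MigrationMetrics:
    """The four migration parameters of one track."""

    track_length: float  # um
    displacement_length: float  # um
    max_speed: float  # um/min
    straightness: float  # dimensionless, NaN when track_length == 0


def track_metrics(track: Track) -> MigrationMetrics:
    """Compute the four migration parameters for one track.

    Requires >= 2 samples.  ``straightness`` is NaN for a track whose
    total path length is zero (the ratio is undefined at 0/0).
    """
    if len(track) < 2:
        raise ValueError(f"track {track.cell_id}: metrics need >= 2 samples")
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    steps = np.hypot(dx, dy)
    durations_min = np.diff(track.t) / 60.0
    track_length = float(steps.sum())
    displacement = float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    max_speed = float((steps / durations_min).max())
    straightness = displacement / track_length if track_length > 0 else float("nan")
    return MigrationMetrics(track_length, displacement, max_speed, straightness)


def summarize(track_set: TrackSet, condition: str = "") -> tuple[pd.DataFrame, pd.Series]:
    """Per-track metrics table plus per-condition medians.

    Zero-length tracks contribute NaN straightness and are excluded
    from the straightness median (count retained in the table).
    """
    if len(track_set) == 0:
        raise ValueError("summarize needs at least one track")
    rows = []
    for tr in track_set:
        m = track_metrics(tr)
        rows.append(
            {
                "cell_id": tr.cell_id,
                "condition": condition,
                "track_length_um": m.track_length,
                "displacement_um": m.displacement_length,
                "max_speed_um_min": m.max_speed,
                "straightness": m.straightness,
            }
        )
    table = pd.DataFrame(rows)
    medians = table[list(METRIC_NAMES)].median()  # NaN-skipping
    return table, medians


def migration_index(n_migrated_treated: int, n_migrated_control: int) -> float:
    """Transwell migration index: treated count / control count."""
    if n_migrated_control <= 0:
        raise ValueError(
            "migration index undefined: control migrated-cell count must be > 0"
        )
    if n_migrated_treated < 0:
        raise ValueError("migrated-cell counts must be >= 0")
    return n_migrated_treated / n_migrated_control


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Rank-based H test across >= 2 groups, with tie correction.

    Returns (H, p).  Completely tied data give H = 0, p = 1 rather
    than an error.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group needs >= 1 observation")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def four_param_logistic(dose, top, bottom, ec50, hill):
    """Variable-slope logistic: bottom + (top - bottom) / (1 + (d/ec50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted four-parameter logistic curve.

    ``hill`` > 0 corresponds to an inhibitory curve descending from
    ``top`` at low dose to ``bottom`` at high dose.
    """

    top: float
    bottom: float
    ec50: float  # uM, > 0
    hill: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.rss < 0:
            raise ValueError(f"rss must be >= 0, got {self.rss}")

    def predict(self, dose):
        return four_param_logistic(dose, self.top, self.bottom, self.ec50, self.hill)


def fit_dose_response(doses, responses) -> DoseResponseFit:
    """Least-squares four-parameter logistic fit on log-dose.

    Initialisation is deterministic: top = max response, bottom = min
    response, ec50 = the dose whose mean response is nearest the
    half-range crossing, hill = 1; the fit is therefore reproducible.
    Needs >= 4 distinct positive doses (four free parameters); constant
    responses are rejected (the slope is unidentifiable).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have the same length")
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0 (fit runs on log-dose)")
    if np.unique(doses).size < 4:
        raise ValueError(
            f"need >= 4 distinct doses for 4 free parameters, got {np.unique(doses).size}"
        )
    if np.ptp(responses) == 0:
        raise ValueError("constant responses: hill slope unidentifiable")

    # deterministic initialiser
    top0 = float(responses.max())
    bottom0 = float(responses.min())
    half = (top0 + bottom0) / 2.0
    per_dose = pd.Series(responses).groupby(pd.Series(doses)).mean()
    ec50_0 = float(per_dose.index[np.argmin(np.abs(per_dose.to_numpy() - half))])

    def residuals(theta):
        top, bottom, log_ec50, hill = theta
        return four_param_logistic(doses, top, bottom, np.exp(log_ec50), hill) - responses

    result = optimize.least_squares(
        residuals,
        x0=[top0, bottom0, np.log(ec50_0), 1.0],
        method="lm",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=10000,
    )
    if not result.success:
        raise RuntimeError(f"dose-response fit did not converge: {result.message}")
    top, bottom, log_ec50, hill = result.x
    rss = float(np.sum(result.fun**2))
    return DoseResponseFit(
        top=float(top), bottom=float(bottom), ec50=float(np.exp(log_ec50)),
        hill=float(hill), rss=rss,
    )
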