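"""Biased persistent random-walk simulator with per-frame ground truth.

Heading update rule: the new heading is drawn from a von Mises
distribution centred on the direction of the resultant vector

    v = persistence_kappa * u(heading_k) + bias_kappa * u(dir to source)

with concentration |v|, where u() is the unit vector of an angle.  With
bias_kappa = 0 this reduces to an unbiased persistent walk; with both
concentrations 0 the heading is uniform (isotropic walk).  Step lengths
are gamma distributed with mean speed_mean*dt and sd speed_sd*dt
(deterministic when speed_sd = 0); arrested cells take zero-length
steps while their heading — and hence the polarity axis — stays frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import MotilityParams
from .tracks import Track, TrackSet

__all__ = ["GroundTruth", "simulate_tracks", "simulate_dose_response_table"]

#: default region (um) in which cells are seeded at frame 0
DEFAULT_START_BOX = ((30.0, 170.0), (30.0, 170.0))


@dataclass
class GroundTruth:
    """Per-cell generative parameters and per-frame true state.

    ``frames`` has one row per cell per frame with columns
    cell_id, frame, x_um, y_um, heading_deg, polarity_axis_deg,
    polarity_amplitude.  Headings are directions of unit vectors in the
    image coordinate frame (x right, y down, degrees CCW from +x in
    the mathematical convention).
    """

    params: dict[int, MotilityParams]
    frames: pd.DataFrame


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees to (-180, 180]."""
    w = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(w == -180.0, 180.0, w)


def simulate_tracks(
    params: MotilityParams,
    n_cells: int,
    n_frames: int,
    dt: float,
    source_point: tuple[float, float] | None = None,
    seed: int = 0,
    start_box: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_START_BOX,
    pixel_size: float = 1.0,
) -> tuple[TrackSet, GroundTruth]:
    """Simulate ``n_cells`` biased persistent random walks.

    Parameters
    ----------
    params
        Motility parameters shared by all simulated cells.
    n_cells, n_frames
        Number of cells (>= 1) and frames (>= 2).
    dt
        Frame interval in seconds (> 0).
    source_point
        Chemokine source position (um); required for bias_kappa > 0 to
        have an effect.
    seed
        Seed for the trajectory random stream; identical inputs give
        bit-identical output.
    start_box
        ((xmin, xmax), (ymin, ymax)) region (um) for initial positions.

    Returns
    -------
    (TrackSet, GroundTruth)
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")

    rng = np.random.default_rng(seed)
    (xmin, xmax), (ymin, ymax) = start_box
    n = n_cells
    dt_min = dt / 60.0  # minutes
    step_mean = params.speed_mean * dt_min
    step_sd = params.speed_sd * dt_min

    xs = np.empty((n_frames, n))
    ys = np.empty((n_frames, n))
    headings = np.empty((n_frames, n))

    xs[0] = rng.uniform(xmin, xmax, n)
    ys[0] = rng.uniform(ymin, ymax, n)
    theta = rng.uniform(-np.pi, np.pi, n)
    headings[0] = theta

    for k in range(n_frames - 1):
        if params.arrested or step_mean == 0.0:
            step = np.zeros(n)
        elif step_sd == 0.0:
            step = np.full(n, step_mean)
        else:
            shape = (step_mean / step_sd) ** 2
            scale = step_sd**2 / step_mean
            step = rng.gamma(shape, scale, n)
        xs[k + 1] = xs[k] + step * np.cos(theta)
        ys[k + 1] = ys[k] + step * np.sin(theta)

        if params.arrested:
            pass  # heading (and polarity axis) frozen
        elif np.isinf(params.persistence_kappa) and params.bias_kappa == 0.0:
            pass  # infinite-persistence limit: deterministic heading
        else:
            vx = params.persistence_kappa * np.cos(theta)
            vy = params.persistence_kappa * np.sin(theta)
            if params.bias_kappa > 0.0 and source_point is not None:
                phi = np.arctan2(source_point[1] - ys[k + 1], source_point[0] - xs[k + 1])
                vx = vx + params.bias_kappa * np.cos(phi)
                vy = vy + params.bias_kappa * np.sin(phi)
            kappa_eff = np.hypot(vx, vy)
            mu = np.where(kappa_eff > 0, np.arctan2(vy, vx), 0.0)
            theta = mu + rng.vonmises(0.0, kappa_eff)
        headings[k + 1] = theta

    t = np.arange(n_frames) * dt
    frames_idx = np.arange(n_frames)
    tracks = [
        Track(cell_id=i, t=t, x=xs[:, i], y=ys[:, i], frames=frames_idx)
        for i in range(n)
    ]
    track_set = TrackSet(
        tracks=tracks, dt=dt, pixel_size=pixel_size, source_point=source_point
    )

    heading_deg = _wrap_deg(np.degrees(headings))
    axis_deg = _wrap_deg(heading_deg + (180.0 if params.polarity_sign == 1 else 0.0))
    gt = pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n), n_frames),
            "frame": np.tile(frames_idx, n),
            "x_um": xs.T.ravel(),
            "y_um": ys.T.ravel(),
            "heading_deg": heading_deg.T.ravel(),
            "polarity_axis_deg": axis_deg.T.ravel(),
            "polarity_amplitude": params.polarity_amplitude,
        }
    )
    truth = GroundTruth(params={i: params for i in range(n)}, frames=gt)
    return track_set, truth


def simulate_dose_response_table(
    doses,
    true_fit,
    noise_sd: float,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw noisy responses around a four-parameter logistic curve.

    Parameters
    ----------
    doses : sequence of float
        Inhibitor concentrations in uM, all > 0 (log-dose must exist).
    true_fit : DoseResponseFit or object with top/bottom/ec50/hill
        The generating curve.
    noise_sd : float
        SD of additive Gaussian noise, response units.
    replicates : int
        Responses per dose (>= 1).

    Returns
    -------
    DataFrame with columns dose_um, replicate, response.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0 (log-dose undefined at 0)")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    from .motility import four_param_logistic

    rng = np.random.default_rng(seed)
    d = np.repeat(doses, replicates)
    mu = four_param_logistic(d, true_fit.top, true_fit.bottom, true_fit.ec50, true_fit.hill)
    resp = mu + (rng.normal(0.0, noise_sd, d.size) if noise_sd > 0 else 0.0)
    return pd.DataFrame(
        {
            "dose_um": d,
            "replicate": np.tile(np.arange(replicates), doses.size),
            "response": resp,
        }
    )
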