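"""Chemotaxis directionality: deviation angles and the Rayleigh test.

Each cell contributes one angle: the signed deviation of its
start-to-end migration direction from the direction toward the
chemokine source (source = 0 degrees).  Coordinated migration toward
the source concentrates the angles near zero; the Rayleigh test for
circular uniformity quantifies this via the mean resultant length

    R_bar = | (1/n) * sum_i (cos theta_i, sin theta_i) |

with test statistic z = n * R_bar^2 and the second-order small-sample
p approximation

    p = exp(-z) * [1 + (2z - z^2)/(4n)
                     - (24z - 132 z^2 + 76 z^3 - 9 z^4)/(288 n^2)]

clipped to (0, 1].  Internally angles live in the mathematical frame
(positive = counterclockwise from the source direction); the display
convention with the source drawn upward is a plotting concern only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import TrackSet

__all__ = ["AngularSample", "RayleighResult", "deviation_angles", "rayleigh_test",
           "rayleigh_p", "rose_counts"]

#: p-values below this are reported as the floor; the correction
#: polynomial can go non-positive at very large z.
P_FLOOR = 1e-12


@dataclass
class AngularSample:
    """Deviation angles (degrees in (-180, 180]) with exclusion audit."""

    angles: np.ndarray
    n_excluded: int = 0
    table: pd.DataFrame | None = None  # cell_id, deviation_deg, displacement_um, included

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (
            np.any(self.angles <= -180.0) or np.any(self.angles > 180.0)
        ):
            raise ValueError("angles must lie in (-180, 180]")

    def __len__(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class RayleighResult:
    n: int
    mean_resultant_length: float  # R_bar in [0, 1]
    mean_direction: float  # degrees in (-180, 180]
    z: float  # n * R_bar^2
    p_value: float  # in (0, 1]


def _signed_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Signed angle (deg) from vector a to vector b, CCW positive, in (-180, 180]."""
    cross = a[0] * b[1] - a[1] * b[0]
    dot = a[0] * b[0] + a[1] * b[1]
    ang = np.degrees(np.arctan2(cross, dot))
    return 180.0 if ang == -180.0 else float(ang)


def deviation_angles(
    track_set: TrackSet,
    source_point: tuple[float, float] | None = None,
    min_displacement: float = 2.0,
) -> AngularSample:
    """One deviation angle per sufficiently motile track.

    The migration direction is the end-minus-start displacement; the
    reference direction points from the track start to the source.
    Tracks displacing less than ``min_displacement`` um are excluded
    (the direction of a near-stationary cell is noise) and counted.
    """
    if source_point is None:
        source_point = track_set.source_point
    if source_point is None:
        raise ValueError("deviation_angles needs a source_point")
    src = np.asarray(source_point, dtype=float)

    angles, rows = [], []
    n_excl = 0
    for tr in track_set:
        if len(tr) < 2:
            n_excl += 1
            continue
        start = np.array([tr.x[0], tr.y[0]])
        disp = np.array([tr.x[-1] - tr.x[0], tr.y[-1] - tr.y[0]])
        displacement = float(np.hypot(*disp))
        included = displacement >= min_displacement
        dev = np.nan
        if included:
            to_source = src - start
            dev = _signed_angle_deg(to_source, disp)
            angles.append(dev)
        else:
            n_excl += 1
        rows.append(
            {
                "cell_id": tr.cell_id,
                "deviation_deg": dev,
                "displacement_um": displacement,
                "included": int(included),
            }
        )
    return AngularSample(
        angles=np.array(angles), n_excluded=n_excl, table=pd.DataFrame(rows)
    )


def rayleigh_p(z: float, n: int) -> float:
    """Second-order corrected Rayleigh p-value, clipped to [P_FLOOR, 1]."""
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(np.clip(p, P_FLOOR, 1.0))


def rayleigh_test(sample) -> RayleighResult:
    """Rayleigh test of circular uniformity on a sample of angles.

    Accepts an :class:`AngularSample` or a plain sequence of angles in
    degrees.  Requires n >= 5 (the small-sample correction is
    unreliable below that).
    """
    angles = sample.angles if isinstance(sample, AngularSample) else np.asarray(sample, float)
    n = angles.size
    if n < 5:
        raise ValueError(
            f"Rayleigh test needs n >= 5 angles (got {n}); "
            "collect more tracks or lower the displacement cutoff"
        )
    rad = np.radians(angles)
    c = np.cos(rad).mean()
    s = np.sin(rad).mean()
    r_bar = float(np.hypot(c, s))
    z = n * r_bar**2
    mean_dir = float(np.degrees(np.arctan2(s, c)))
    if mean_dir == -180.0:
        mean_dir = 180.0
    return RayleighResult(
        n=n,
        mean_resultant_length=r_bar,
        mean_direction=mean_dir,
        z=float(z),
        p_value=rayleigh_p(z, n),
    )


def rose_counts(sample, n_bins: int = 8) -> np.ndarray:
    """Sector counts for a circular (rose) histogram.

    ``n_bins`` must be >= 4 and divide 360 evenly; bins tile
    (-180, 180] and counts sum to the sample size.
    """
    if n_bins < 4 or 360 % n_bins != 0:
        raise ValueError(f"n_bins must be >= 4 and divide 360, got {n_bins}")
    angles = sample.angles if isinstance(sample, AngularSample) else np.asarray(sample, float)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # (-180, 180] binning: shift left-closed histogram by flipping sign
    counts, _ = np.histogram(-angles, bins=edges)
    return counts[::-1]
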