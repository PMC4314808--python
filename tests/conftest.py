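import numpy as np
import pandas as pd
import pytest

from pcpmig.render import NoiseModel, render_frames
from pcpmig.simulate import GroundTruth
from pcpmig.tracks import Track, TrackSet


@pytest.fixture
def make_single_cell_stack():
    """Factory: a stationary rendered cell with prescribed polarity.

    Returns (stack, track, headings) for one cell at (50, 50) um with
    the given polarity amplitude/sign and heading along +x.
    """

    def _make(
        amplitude=0.3,
        polarity_sign=1,
        heading_deg=0.0,
        n_frames=2,
        pixel_size=0.5,
        cell_radius=10.0,
        ring_width=2.0,
        gaussian_sd=0.0,
        image_shape=(200, 200),
        seed=0,
        center=(50.0, 50.0),
    ):
        cx, cy = center
        track = Track(
            0,
            t=np.arange(n_frames) * 30.0,
            x=np.full(n_frames, cx),
            y=np.full(n_frames, cy),
            frames=np.arange(n_frames),
        )
        ts = TrackSet([track], dt=30.0, pixel_size=pixel_size)
        axis = heading_deg + (180.0 if polarity_sign == 1 else 0.0)
        gt = GroundTruth(
            params={0: None},
            frames=pd.DataFrame(
                {
                    "cell_id": 0,
                    "frame": np.arange(n_frames),
                    "x_um": cx,
                    "y_um": cy,
                    "heading_deg": heading_deg,
                    "polarity_axis_deg": axis,
                    "polarity_amplitude": amplitude,
                }
            ),
        )
        stack = render_frames(
            ts,
            gt,
            cell_radius=cell_radius,
            base_intensity=1000.0,
            noise_model=NoiseModel(gaussian_sd=gaussian_sd),
            image_shape=image_shape,
            seed=seed,
            ring_width=ring_width,
        )
        rad = np.radians(heading_deg)
        headings = [np.array([np.cos(rad), np.sin(rad)])] * n_frames
        return stack, track, headings

    return _make


def half_ring_ratio(amplitude: float) -> float:
    """Closed-form trailing/leading mean-intensity ratio of the ring model.

    Averaging 1 + A*cos(phi) over the half-circle centred on the peak
    gives 1 + 2A/pi, and 1 - 2A/pi over the opposite half.
    """
    return (1 + 2 * amplitude / np.pi) / (1 - 2 * amplitude / np.pi)
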