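"""Rendering geometry, detection accuracy and linking against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pcpmig.detect import detect_cells
from pcpmig.link import LinkingConfig, heading_at, link_detections, track_headings
from pcpmig.params import condition_preset
from pcpmig.render import NoiseModel, render_frames, read_stack, write_stack
from pcpmig.simulate import GroundTruth, simulate_tracks
from pcpmig.tracks import Track, TrackSet


def two_cell_truth(positions, n_frames=1, amplitude=0.0):
    """GroundTruth for stationary cells at the given (x, y) um positions."""
    rows = []
    tracks = []
    for cid, (x, y) in enumerate(positions):
        for f in range(n_frames):
            rows.append(
                dict(cell_id=cid, frame=f, x_um=x, y_um=y, heading_deg=0.0,
                     polarity_axis_deg=180.0, polarity_amplitude=amplitude)
            )
        tracks.append(
            Track(cid, t=np.arange(n_frames) * 30.0, x=np.full(n_frames, x),
                  y=np.full(n_frames, y), frames=np.arange(n_frames))
        )
    ts = TrackSet(tracks, dt=30.0, pixel_size=1.0)
    return ts, GroundTruth(params={}, frames=pd.DataFrame(rows))


class TestRender:
    def test_uniform_ring_has_symmetric_halves(self):
        ts, gt = two_cell_truth([(50.0, 50.0)], amplitude=0.0)
        stack = render_frames(ts, gt, cell_radius=10.0, image_shape=(100, 100))
        pol = stack.channel("polarity_marker")[0]
        left, right = pol[:, :50], pol[:, 50:]
        assert left.sum() > 0
        assert left[left > 0].mean() == pytest.approx(right[right > 0].mean(), rel=1e-12)

    def test_distant_cells_render_disjoint(self):
        ts, gt = two_cell_truth([(30.0, 30.0), (130.0, 130.0)])
        stack = render_frames(ts, gt, cell_radius=10.0, image_shape=(160, 160))
        from skimage.measure import label

        trk = stack.channel("cell_tracker")[0]
        assert label(trk > 0).max() == 2

    def test_rejects_subpixel_radius(self):
        ts, gt = two_cell_truth([(50.0, 50.0)])
        with pytest.raises(ValueError, match="2 px"):
            render_frames(ts, gt, cell_radius=1.5, image_shape=(100, 100))

    def test_noise_seed_reproducible_and_non_negative(self):
        ts, gt = two_cell_truth([(50.0, 50.0)], n_frames=3)
        kw = dict(cell_radius=8.0, image_shape=(100, 100),
                  noise_model=NoiseModel(gaussian_sd=50.0, poisson_scaling=True))
        a = render_frames(ts, gt, seed=7, **kw)
        b = render_frames(ts, gt, seed=7, **kw)
        assert np.array_equal(a.data, b.data)
        assert a.data.min() >= 0

    def test_stack_roundtrip_through_tiff(self, tmp_path):
        ts, gt = two_cell_truth([(50.0, 50.0)], n_frames=4)
        stack = render_frames(ts, gt, cell_radius=8.0, image_shape=(100, 100))
        write_stack(stack, tmp_path, prefix="s")
        back = read_stack(tmp_path, prefix="s")
        assert back.data.shape == stack.data.shape
        assert back.pixel_size == stack.pixel_size
        assert back.dt == stack.dt
        # 16-bit quantisation only
        assert np.max(np.abs(back.data - np.round(stack.data))) == 0


class TestDetect:
    def test_single_disc_centroid_recovered(self):
        ts, gt = two_cell_truth([(50.0, 50.0)])
        stack = render_frames(ts, gt, cell_radius=8.0, image_shape=(100, 100))
        det = detect_cells(stack)
        assert len(det) == 1
        assert det.x_um.iloc[0] == pytest.approx(50.0, abs=0.5)
        assert det.y_um.iloc[0] == pytest.approx(50.0, abs=0.5)

    def test_two_separated_discs_two_detections(self):
        ts, gt = two_cell_truth([(30.0, 30.0), (120.0, 120.0)])
        stack = render_frames(ts, gt, cell_radius=8.0, image_shape=(160, 160))
        assert len(detect_cells(stack)) == 2

    def test_min_area_filter_removes_all(self):
        ts, gt = two_cell_truth([(50.0, 50.0)])
        stack = render_frames(ts, gt, cell_radius=8.0, image_shape=(100, 100))
        disc_area = np.pi * 8.0**2
        assert len(detect_cells(stack, min_area=2 * disc_area)) == 0

    def test_all_zero_frames_yield_no_detections(self):
        from pcpmig.render import FrameStack

        stack = FrameStack(np.zeros((3, 2, 50, 50)), pixel_size=1.0, dt=30.0)
        assert len(detect_cells(stack)) == 0


def brute_force_cost(det, max_disp):
    """Exhaustive minimum total link distance over per-frame matchings.

    For instances where every consecutive frame holds the same cells
    and every true match is within max_disp, the optimum decomposes
    over frame pairs; each pair is solved by enumerating permutations.
    """
    total = 0.0
    frames = sorted(det.frame.unique())
    for fa, fb in zip(frames[:-1], frames[1:]):
        a = det[det.frame == fa][["x_um", "y_um"]].to_numpy()
        b = det[det.frame == fb][["x_um", "y_um"]].to_numpy()
        best = np.inf
        for perm in itertools.permutations(range(len(b))):
            d = sum(np.hypot(*(a[i] - b[j])) for i, j in enumerate(perm))
            best = min(best, d)
        total += best
    return total


def greedy_cost(track_set):
    return sum(
        np.hypot(np.diff(tr.x), np.diff(tr.y)).sum() for tr in track_set
    )


class TestLink:
    def make_detections(self, positions_by_frame):
        rows = []
        for f, pos in enumerate(positions_by_frame):
            for lbl, (x, y) in enumerate(pos, start=1):
                rows.append(dict(frame=f, label=lbl, x_um=x, y_um=y,
                                 area_um2=100.0, mean_ch0=1.0, mean_ch1=1.0))
        return pd.DataFrame(rows)

    def test_well_separated_cells_recover_ground_truth(self):
        ts, gt = simulate_tracks(
            condition_preset("control"), 4, 8, 30.0, seed=2,
            start_box=((30.0, 60.0), (30.0, 60.0)),
        )
        # spread the cells far apart so matching is unambiguous
        for i, tr in enumerate(ts):
            tr.x += 200.0 * (i % 2)
            tr.y += 200.0 * (i // 2)
        det = self.make_detections(
            [[(tr.x[f], tr.y[f]) for tr in ts] for f in range(8)]
        )
        linked = link_detections(det, LinkingConfig(max_disp=15.0), dt=30.0)
        assert len(linked) == 4
        got = sorted(tuple(np.round(tr.x, 6)) for tr in linked)
        want = sorted(tuple(np.round(tr.x, 6)) for tr in ts)
        assert got == want

    def test_greedy_within_10pct_of_brute_force(self):
        rng = np.random.default_rng(0)
        for case in range(20):
            n_cells = rng.integers(2, 5)
            n_frames = rng.integers(3, 7)
            pos = rng.uniform(0, 100, (n_cells, 2))
            frames = []
            for _ in range(n_frames):
                pos = pos + rng.uniform(-4, 4, pos.shape)
                frames.append([tuple(p) for p in pos])
            det = self.make_detections(frames)
            linked = link_detections(
                det, LinkingConfig(max_disp=500.0, min_track_len=2), dt=30.0
            )
            g = greedy_cost(linked)
            opt = brute_force_cost(det, 500.0)
            assert g <= 1.10 * opt + 1e-9, f"case {case}: greedy {g} vs optimal {opt}"

    def test_gap_bridging_keeps_single_track(self):
        frames = [[(10.0, 10.0)], [(12.0, 10.0)], [], [(16.0, 10.0)]]
        det = self.make_detections(frames)
        linked = link_detections(det, LinkingConfig(max_disp=5.0, max_gap=1), dt=30.0)
        assert len(linked) == 1
        assert len(linked.tracks[0]) == 3

    def test_no_gap_bridging_splits_track(self):
        frames = [[(10.0, 10.0)], [(12.0, 10.0)], [], [(16.0, 10.0)], [(18.0, 10.0)]]
        det = self.make_detections(frames)
        linked = link_detections(det, LinkingConfig(max_disp=5.0, max_gap=0), dt=30.0)
        assert len(linked) == 2

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        frames = []
        pos = rng.uniform(0, 80, (4, 2))
        for _ in range(5):
            pos = pos + rng.uniform(-3, 3, pos.shape)
            frames.append([tuple(p) for p in pos])
        det = self.make_detections(frames)
        shuffled = det.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = link_detections(det, LinkingConfig(max_disp=50.0), dt=30.0)
        b = link_detections(shuffled, LinkingConfig(max_disp=50.0), dt=30.0)
        assert len(a) == len(b)
        for tr_a, tr_b in zip(a, b):
            assert np.array_equal(tr_a.x, tr_b.x)
            assert np.array_equal(tr_a.y, tr_b.y)

    def test_each_detection_used_at_most_once(self):
        rng = np.random.default_rng(5)
        frames = [[tuple(p) for p in rng.uniform(0, 50, (3, 2))] for _ in range(4)]
        det = self.make_detections(frames)
        linked = link_detections(det, LinkingConfig(max_disp=100.0), dt=30.0)
        used = sum(len(tr) for tr in linked)
        assert used <= len(det)

    def test_empty_input_gives_empty_trackset(self):
        linked = link_detections(pd.DataFrame(), LinkingConfig(), dt=30.0)
        assert len(linked) == 0


class TestHeadingAt:
    def test_straight_track_heads_plus_x(self):
        tr = Track(0, t=np.arange(5) * 30.0, x=np.arange(5) * 3.0, y=np.zeros(5))
        for i in range(1, 5):
            h = heading_at(tr, i, min_step=1.0)
            assert np.allclose(h, [1.0, 0.0])

    def test_first_sample_heading_undefined(self):
        tr = Track(0, t=np.arange(3) * 30.0, x=np.arange(3) * 3.0, y=np.zeros(3))
        assert heading_at(tr, 0, min_step=1.0) is None

    def test_arrested_after_motion_reuses_pre_arrest_heading(self):
        x = np.array([0.0, 3.0, 3.0, 3.0, 3.0])
        tr = Track(0, t=np.arange(5) * 30.0, x=x, y=np.zeros(5))
        for i in range(2, 5):
            assert np.allclose(heading_at(tr, i, min_step=1.0), [1.0, 0.0])

    def test_stationary_from_birth_is_undefined_everywhere(self):
        tr = Track(0, t=np.arange(4) * 30.0, x=np.zeros(4), y=np.zeros(4))
        assert all(h is None for h in track_headings(tr, min_step=1.0))

    def test_subpixel_jitter_does_not_flip_heading(self):
        x = np.array([0.0, 3.0, 3.1, 2.95, 3.05])
        tr = Track(0, t=np.arange(5) * 30.0, x=x, y=np.zeros(5))
        for i in range(1, 5):
            h = heading_at(tr, i, min_step=1.0)
            assert h[0] > 0.99
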