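"""Rendering and ROI densitometry."""
import numpy as np
import pytest

from tailbeat.acquisition import (
    FrameStack, RenderGeometry, ROISpec,
    measure_roi_density, place_rois, read_tiff, render_frames, write_tiff,
)
from tailbeat.errors import ParameterError
from tailbeat.trace import BilateralTrace, make_time_grid

from conftest import circular_diff, sine_pair

RATE = 500.0


def flat_trace(n=20, value=1.0):
    t = make_time_grid(n, RATE)
    x = np.full(n, value)
    return BilateralTrace(t=t, left=x, right=x.copy(), rate_hz=RATE)


class TestRender:
    def test_equal_sides_tail_straight_all_frames_identical(self):
        stack = render_frames(flat_trace())
        assert np.all(stack.frames == stack.frames[0])
        g = RenderGeometry()
        cols = np.nonzero(stack.frames[0].max(axis=0))[0]
        # straight tail: bright pixels hug the pivot column
        assert abs(cols.mean() - g.pivot_x) < 2

    def test_left_burst_deflects_to_image_left(self):
        n = 40
        t = make_time_grid(n, RATE)
        left = np.zeros(n)
        left[10:30] = 1.0
        tr = BilateralTrace(t=t, left=left, right=np.zeros(n), rate_hz=RATE)
        stack = render_frames(tr)
        g = RenderGeometry()
        frame = stack.frames[20]          # mid-burst
        row = frame[g.pivot_y + g.tail_len_px - 2]
        tip_x = np.average(np.arange(len(row)), weights=row + 1e-9)
        assert tip_x < g.pivot_x - 5

    def test_sine_tip_period_matches_input_by_centroid_oracle(self):
        tr = sine_pair(10.0, 0.5, n=1500)
        # shift to nonnegative activations as the renderer normalizes per side
        tr = BilateralTrace(t=tr.t, left=tr.left + 1.1, right=tr.right + 1.1,
                            rate_hz=RATE)
        stack = render_frames(tr)
        g = RenderGeometry()
        band = stack.frames[:, g.pivot_y + g.tail_len_px - 6:
                            g.pivot_y + g.tail_len_px + 2, :].astype(float)
        w = band.sum(axis=1)
        tip_x = (w * np.arange(w.shape[1])).sum(axis=1) / w.sum(axis=1)
        spec = np.abs(np.fft.rfft(tip_x - tip_x.mean())) ** 2
        freqs = np.fft.rfftfreq(len(tip_x), 1 / RATE)
        f_dom = freqs[np.argmax(spec)]
        assert abs(1 / f_dom - 0.1) <= 1 / RATE

    def test_geometry_validation(self):
        with pytest.raises(ParameterError):
            RenderGeometry(tail_len_px=300)     # tail below frame
        with pytest.raises(ParameterError):
            RenderGeometry(max_deflect_px=300)  # tip leaves frame


class TestROI:
    def test_all_black_stack_gives_zero_traces(self):
        stack = FrameStack(frames=np.zeros((10, 40, 60), dtype=np.uint8),
                           rate_hz=RATE)
        dens = measure_roi_density(stack, ROISpec("left", 0, 0, 10, 40),
                                   ROISpec("right", 50, 0, 60, 40))
        assert np.all(dens.left == 0) and np.all(dens.right == 0)

    def test_single_bright_pixel_occupancy(self):
        frames = np.zeros((30, 40, 60), dtype=np.uint8)
        frames[10:20, 5, 5] = 255     # inside the left ROI on frames 10..19
        stack = FrameStack(frames=frames, rate_hz=RATE)
        dens = measure_roi_density(stack, ROISpec("left", 0, 0, 10, 40),
                                   ROISpec("right", 50, 0, 60, 40))
        expected = np.zeros(30)
        expected[10:20] = 255 / (10 * 40)
        np.testing.assert_allclose(dens.left, expected)
        assert np.all(dens.right == 0)

    def test_linearity_in_intensity(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 60, size=(10, 40, 60)).astype(np.uint8)
        rl, rr = ROISpec("left", 0, 0, 10, 40), ROISpec("right", 50, 0, 60, 40)
        d1 = measure_roi_density(FrameStack(frames=base, rate_hz=RATE), rl, rr)
        d3 = measure_roi_density(
            FrameStack(frames=3 * base, rate_hz=RATE), rl, rr)
        np.testing.assert_allclose(d3.left, 3 * d1.left)
        np.testing.assert_allclose(d3.right, 3 * d1.right)

    def test_overlapping_rois_rejected(self):
        stack = FrameStack(frames=np.zeros((5, 40, 60), dtype=np.uint8),
                           rate_hz=RATE)
        with pytest.raises(ParameterError, match="overlap"):
            measure_roi_density(stack, ROISpec("left", 0, 0, 30, 40),
                                ROISpec("right", 20, 0, 60, 40))

    def test_roi_outside_frame_rejected(self):
        stack = FrameStack(frames=np.zeros((5, 40, 60), dtype=np.uint8),
                           rate_hz=RATE)
        with pytest.raises(ParameterError, match="outside"):
            measure_roi_density(stack, ROISpec("left", 0, 0, 10, 40),
                                ROISpec("right", 55, 0, 70, 40))


@pytest.fixture(scope="module")
def rendered(intact_trace):
    stack = render_frames(intact_trace)
    rl, rr = place_rois(intact_trace)
    return intact_trace, stack, rl, rr


class TestRoundTrip:
    def test_roundtrip_period_and_phase(self, rendered):
        from tailbeat.rhythm import analyze_trace

        tr, stack, rl, rr = rendered
        dens = measure_roi_density(stack, rl, rr)
        direct = analyze_trace(tr, seed=0)
        via_roi = analyze_trace(dens, seed=0)
        assert abs(via_roi.period_s - direct.period_s) <= 0.05 * direct.period_s
        assert circular_diff(via_roi.phase, direct.phase) <= 0.03

    def test_roi_swap_mirrors_phase(self, rendered):
        from tailbeat.rhythm import analyze_trace

        tr, stack, rl, rr = rendered
        dens = measure_roi_density(stack, rl, rr)
        rl2 = ROISpec("right", rl.x0, rl.y0, rl.x1, rl.y1)
        rr2 = ROISpec("left", rr.x0, rr.y0, rr.x1, rr.y1)
        swapped = measure_roi_density(stack, rr2, rl2)
        p1 = analyze_trace(dens, seed=0).phase
        p2 = analyze_trace(swapped, seed=0).phase
        assert circular_diff(p2, (1 - p1) % 1.0) <= 0.02


class TestTiff:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        frames = rng.integers(0, 256, size=(6, 32, 48)).astype(np.uint8)
        stack = FrameStack(frames=frames, rate_hz=400.0)
        path = tmp_path / "stack.tif"
        write_tiff(stack, path)
        back = read_tiff(path)
        np.testing.assert_array_equal(back.frames, frames)
        assert back.rate_hz == 400.0
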