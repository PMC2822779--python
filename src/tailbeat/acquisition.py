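"""Synthetic measurement chain: rendered tail-swing frames and ROI densitometry.

The original recordings imaged a tethered larva at 400-500 fps and measured
mean brightness in two rectangular regions of interest placed at the points of
maximum left and right tail excursion; the two density traces are the
left/right activity signals.  This module closes that loop synthetically: it
renders a schematic bright tail on a dark background whose tip deflection
follows the (left - right) activation difference of a
:class:`~tailbeat.trace.BilateralTrace`, and recovers a bilateral trace from
two ROIs, so the full simulate -> film -> densitometry -> rhythm-analysis
pipeline can be tested end to end.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter1d
from skimage.draw import line_aa

from .errors import ParameterError
from .trace import BilateralTrace, make_time_grid

__all__ = [
    "RenderGeometry",
    "FrameStack",
    "ROISpec",
    "render_frames",
    "measure_roi_density",
    "place_rois",
    "write_tiff",
    "read_tiff",
]


@dataclass
class RenderGeometry:
    """Image geometry for the schematic tail renderer.

    The tail hangs from a pivot near the top of the frame; its tip deflects
    laterally by up to ``max_deflect_px`` pixels, to the left of the image for
    left-side activation (``deflection ∝ left - right``).  ``bend`` shapes the
    curve (lateral offset grows as ``s**bend`` along the tail).
    """

    width: int = 240
    height: int = 150
    pivot_x: int | None = None      # defaults to width // 2
    pivot_y: int = 8
    tail_len_px: int = 128
    max_deflect_px: int = 80
    bend: float = 1.2
    n_segments: int = 24
    #: activation -> deflection sharpness: deflection follows
    #: ``left**sharpness - right**sharpness`` (per-side normalized).  Muscle
    #: force recruitment is supralinear in activation; values well above 1
    #: keep each side's burst timing distinct in the single tail trajectory.
    sharpness: float = 5.0
    #: Gaussian smoothing (s) of the deflection, mimicking tail inertia.
    smooth_s: float = 0.004

    def __post_init__(self) -> None:
        if self.pivot_x is None:
            self.pivot_x = self.width // 2
        if self.width < 8 or self.height < 8:
            raise ParameterError("width/height: frame too small")
        if not (0 <= self.pivot_x < self.width and 0 <= self.pivot_y < self.height):
            raise ParameterError("pivot: outside the frame")
        if self.tail_len_px < 2:
            raise ParameterError("tail_len_px: must be >= 2")
        if self.pivot_y + self.tail_len_px >= self.height:
            raise ParameterError(
                "tail_len_px: tail extends below the frame "
                f"(pivot_y={self.pivot_y} + tail_len_px={self.tail_len_px} "
                f">= height={self.height})"
            )
        if self.pivot_x - self.max_deflect_px < 0 or \
                self.pivot_x + self.max_deflect_px >= self.width:
            raise ParameterError(
                "max_deflect_px: tail tip can leave the frame laterally")
        if self.bend <= 0:
            raise ParameterError("bend: must be > 0")


@dataclass
class FrameStack:
    """Ordered grayscale frames (T, H, W) uint8 at a fixed frame rate."""

    frames: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ParameterError("frames: need a (T>=2, H, W) array")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ParameterError("frames: intensities must lie in 0..255")
            self.frames = self.frames.astype(np.uint8)
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz: must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class ROISpec:
    """Rectangular region of interest, 0-based, half-open [x0,x1) x [y0,y1)."""

    side: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ParameterError(f"side: must be 'left' or 'right', got {self.side!r}")
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ParameterError("x1/y1: ROI must have positive extent")
        if self.x0 < 0 or self.y0 < 0:
            raise ParameterError("x0/y0: ROI bounds must be >= 0")

    def check_within(self, height: int, width: int) -> None:
        if self.x1 > width or self.y1 > height:
            raise ParameterError(
                f"ROI {self.side}: extends outside the {height}x{width} frame")

    def overlaps(self, other: "ROISpec") -> bool:
        return not (
            self.x1 <= other.x0 or other.x1 <= self.x0
            or self.y1 <= other.y0 or other.y1 <= self.y0
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------
def _normalized_deflection(
    trace: BilateralTrace, sharpness: float = 5.0, smooth_s: float = 0.004
) -> np.ndarray:
    """Tail deflection in [-1, 1] from the left/right activation difference.

    Each side is normalized to its own peak, raised to ``sharpness`` (muscle
    force recruits supralinearly with activation, so the tail trajectory
    keeps each side's burst timing), differenced, smoothed over ``smooth_s``
    (tail inertia), and scaled by the largest magnitude.  Positive values
    deflect the tail to the image's left.
    """
    def side_norm(x: np.ndarray) -> np.ndarray:
        m = np.max(x)
        return x / m if m > 0 else np.zeros_like(x)

    diff = side_norm(trace.left) ** sharpness - side_norm(trace.right) ** sharpness
    if smooth_s > 0:
        diff = gaussian_filter1d(diff, smooth_s * trace.rate_hz)
    scale = np.max(np.abs(diff))
    if scale == 0:
        return np.zeros_like(diff)
    return diff / scale


def _tip_x(geometry: RenderGeometry, deflection: np.ndarray) -> np.ndarray:
    """Tail-tip x coordinate per frame; left activation deflects to smaller x."""
    return geometry.pivot_x - geometry.max_deflect_px * deflection


def render_frames(
    trace: BilateralTrace,
    geometry: RenderGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FrameStack:
    """Render one schematic tail frame per trace sample.

    The tail is a bright anti-aliased curve on a dark background; the tip's
    lateral deflection is proportional to the normalized ``left - right``
    activation (left activation bends the tail to the image's left).
    Optional additive Gaussian pixel noise (``noise_sd``, in intensity units)
    supports robustness tests.  Deterministic given the seed.
    """
    if geometry is None:
        geometry = RenderGeometry()
    g = geometry
    defl = _normalized_deflection(trace, g.sharpness, g.smooth_s)
    n = len(trace)
    frames = np.zeros((n, g.height, g.width), dtype=float)
    s = np.linspace(0.0, 1.0, g.n_segments + 1)
    ys = g.pivot_y + g.tail_len_px * s
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    for i in range(n):
        xs = g.pivot_x - g.max_deflect_px * defl[i] * s ** g.bend
        img = frames[i]
        for k in range(g.n_segments):
            rr, cc, val = line_aa(
                int(round(ys[k])), int(round(xs[k])),
                int(round(ys[k + 1])), int(round(xs[k + 1])),
            )
            np.maximum.at(img, (rr, cc), val * 255.0)
        if rng is not None:
            img += rng.normal(0.0, noise_sd, img.shape)
    np.clip(frames, 0, 255, out=frames)
    return FrameStack(frames=frames.astype(np.uint8), rate_hz=trace.rate_hz)


def place_rois(
    trace: BilateralTrace,
    geometry: RenderGeometry | None = None,
    inner_frac: float = 0.12,
) -> tuple[ROISpec, ROISpec]:
    """ROIs spanning the maximum left and right tail excursion zones.

    Mirrors the experimental setup: one box per side, covering the lateral
    band the lower tail sweeps through from ``inner_frac`` of the observed
    peak excursion out to slightly beyond it, over the lower half of the
    tail.  The measured density then grades with how far the tail has swung
    into that side.
    """
    if geometry is None:
        geometry = RenderGeometry()
    g = geometry
    tip = _tip_x(g, _normalized_deflection(trace, g.sharpness, g.smooth_s))
    excur_l = g.pivot_x - float(np.min(tip))   # leftward peak excursion, px
    excur_r = float(np.max(tip)) - g.pivot_x
    if excur_l < 2 or excur_r < 2:
        raise ParameterError(
            "place_rois: tail excursion too small for disjoint ROIs "
            "(is the trace nearly flat?)"
        )
    y0 = g.pivot_y + g.tail_len_px // 2
    y1 = min(g.height, g.pivot_y + g.tail_len_px + 4)
    left = ROISpec(
        "left",
        max(0, int(g.pivot_x - excur_l - 3)),
        y0,
        int(g.pivot_x - inner_frac * excur_l),
        y1,
    )
    right = ROISpec(
        "right",
        int(g.pivot_x + inner_frac * excur_r) + 1,
        y0,
        min(g.width, int(g.pivot_x + excur_r + 3) + 1),
        y1,
    )
    if left.overlaps(right):
        raise ParameterError("place_rois: computed ROIs overlap")
    return left, right


def measure_roi_density(
    stack: FrameStack, roi_left: ROISpec, roi_right: ROISpec
) -> BilateralTrace:
    """Mean pixel intensity per frame inside each ROI, as a bilateral trace.

    This is the dual-photomultiplier densitometry: the left trace rises when
    the tail sweeps through the left ROI.  ROIs must be disjoint and inside
    the frame.
    """
    if roi_left.side == roi_right.side:
        raise ParameterError("measure_roi_density: need one ROI per side")
    t, h, w = stack.shape
    roi_left.check_within(h, w)
    roi_right.check_within(h, w)
    if roi_left.overlaps(roi_right):
        raise ParameterError("measure_roi_density: ROIs overlap")
    def mean_in(roi: ROISpec) -> np.ndarray:
        return stack.frames[:, roi.y0:roi.y1, roi.x0:roi.x1].mean(axis=(1, 2))
    return BilateralTrace(
        t=make_time_grid(t, stack.rate_hz),
        left=mean_in(roi_left),
        right=mean_in(roi_right),
        rate_hz=stack.rate_hz,
        condition="roi_densitometry",
    )


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------
def write_tiff(stack: FrameStack, path) -> None:
    """Write the stack as a multi-page TIFF; the frame rate is stored in the
    ImageDescription tag."""
    tifffile.imwrite(path, stack.frames,
                     description=f"tailbeat rate_hz={stack.rate_hz}")


def read_tiff(path) -> FrameStack:
    """Read a multi-page TIFF written by :func:`write_tiff`."""
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        desc = tf.pages[0].description or ""
    rate_hz = 0.0
    for token in desc.split():
        if token.startswith("rate_hz="):
            rate_hz = float(token.split("=", 1)[1])
    if rate_hz <= 0:
        raise ParameterError(
            f"{path}: no rate_hz found in the TIFF description tag")
    return FrameStack(frames=frames, rate_hz=rate_hz)
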