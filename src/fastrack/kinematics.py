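"""Track smoothing and locomotion parameters.

Raw centroid tracks wobble by a fraction of a pixel from frame to frame
(segmentation noise on a ~50 px blob). A Gaussian smoothing pass removes
this jitter while displacing the track by far less than a body length, and
instantaneous speed is then read off the smoothed track as displacement
per frame interval, converted to mm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DimensionError, ParameterError
from .tracking import Track


@dataclass
class SmoothedTrack:
    """A track after per-axis Gaussian smoothing (same frames, new x/y)."""

    track_id: int
    points: list[tuple[int, float, float]]
    sigma_frames: float

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SpeedSeries:
    """Instantaneous speeds along one track, in mm/s (length n-1)."""

    track_id: int
    values: np.ndarray
    fps: float
    mm_per_px: float


@dataclass
class SpeedHistogram:
    """Pooled, normalized speed distribution plus the pooled mean."""

    bin_edges: np.ndarray  # length n_bins + 1
    density: np.ndarray    # integrates to 1 over the binned range
    mean: float
    n: int

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_left,bin_right,density\n")
            for lo, hi, d in zip(self.bin_edges[:-1], self.bin_edges[1:], self.density):
                fh.write(f"{lo},{hi},{d}\n")


def _gaussian_kernel(sigma: float) -> np.ndarray:
    """Discrete Gaussian truncated at 4 sigma, normalized to sum 1."""
    radius = max(1, int(math.ceil(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _smooth_axis(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # normalized convolution: renormalize the kernel where it overhangs
    # the track ends instead of padding with invented positions
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def smooth_track(track: Track, sigma_frames: float = 1.0) -> SmoothedTrack:
    """Smooth x and y independently with a discrete Gaussian kernel.

    The kernel is truncated at 4 sigma and renormalized at the track
    boundaries; ``sigma_frames=0`` returns the track unchanged. Frame
    indices and track length are preserved.
    """
    if sigma_frames < 0:
        raise ParameterError(f"sigma_frames must be >= 0, got {sigma_frames}")
    frames = [p[0] for p in track.points]
    x = np.array([p[1] for p in track.points], dtype=np.float64)
    y = np.array([p[2] for p in track.points], dtype=np.float64)

    if sigma_frames > 0 and len(track.points) > 1:
        kernel = _gaussian_kernel(sigma_frames)
        x = _smooth_axis(x, kernel)
        y = _smooth_axis(y, kernel)

    points = [(f, float(xi), float(yi)) for f, xi, yi in zip(frames, x, y)]
    return SmoothedTrack(track.track_id, points, sigma_frames)


def smoothing_displacements(
    original: Track, smoothed: SmoothedTrack, mm_per_px: float
) -> np.ndarray:
    """Per-point Euclidean distance between the original and smoothed
    positions, in micrometres."""
    if len(original) != len(smoothed):
        raise DimensionError(
            f"track lengths differ: {len(original)} vs {len(smoothed)}"
        )
    o = np.array([(x, y) for _, x, y in original.points])
    s = np.array([(x, y) for _, x, y in smoothed.points])
    if len(o) == 0:
        return np.empty(0)
    return np.hypot(*(o - s).T) * mm_per_px * 1000.0


def instantaneous_speed(
    track: SmoothedTrack | Track,
    fps: float,
    mm_per_px: float,
    difference: Literal["forward", "central"] = "forward",
) -> SpeedSeries:
    """Instantaneous speed at each point of the (smoothed) track, mm/s.

    Forward differences (default): speed_i = |p_{i+1} - p_i| * mm_per_px
    * fps, giving n-1 values. Central differences average the neighbouring
    displacements and also give n-1 values aligned the same way at the
    ends.
    """
    if fps <= 0 or mm_per_px <= 0:
        raise ParameterError("fps and mm_per_px must be positive")
    pts = np.array([(x, y) for _, x, y in track.points], dtype=np.float64)
    if len(pts) < 2:
        return SpeedSeries(track.track_id, np.empty(0), fps, mm_per_px)
    steps = np.hypot(*np.diff(pts, axis=0).T)  # px per frame, length n-1
    if difference == "central":
        interior = 0.5 * (steps[:-1] + steps[1:])
        steps = np.concatenate([[steps[0]], interior]) if len(steps) > 1 else steps
    elif difference != "forward":
        raise ParameterError(f"unknown difference scheme {difference!r}")
    return SpeedSeries(track.track_id, steps * mm_per_px * fps, fps, mm_per_px)


def speed_distribution(
    series: Sequence[SpeedSeries], bin_width: float = 0.1
) -> SpeedHistogram:
    """Pool speed series into one normalized histogram (density sums to 1
    over the bins) and report the pooled mean speed."""
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be > 0, got {bin_width}")
    pooled = np.concatenate([s.values for s in series]) if series else np.empty(0)
    if pooled.size == 0:
        return SpeedHistogram(np.array([0.0, bin_width]), np.array([0.0]), 0.0, 0)
    n_bins = max(1, int(math.ceil((pooled.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    density, _ = np.histogram(pooled, bins=edges, density=True)
    return SpeedHistogram(edges, density, float(pooled.mean()), int(pooled.size))
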