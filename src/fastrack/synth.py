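"""Ground-truthed synthetic crawling movies.

Emulates the recording conditions of a transmitted-light larva rig:
640×480 8-bit grayscale frames at 3.75 fps showing dark blobs (larvae) on
a light background, a static high-contrast dish-edge ring, a slow global
brightness beat (mains-driven light output at 2×60 Hz sampled by a ~30 Hz
camera clock with a small detune), and additive pixel noise. Blob contrast
models dye feeding: a dye-fed larva's gut darkens (default depth 0.4 below
background) while an undyed larva is nearly translucent (0.05).

Every movie comes with its exact ground truth (true center per frame and
the static-object pixel set), so detection and tracking can be scored
without real video.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .io_video import DEFAULT_FPS, DEFAULT_MM_PER_PX, Movie
from .tracking import Track


@dataclass
class RingSpec:
    """Static dish-edge annulus: pixels at intensity ``level``.

    The default 12 px thickness (~3.6 mm) models the dish wall plus
    meniscus band, wide enough that a crawling blob is briefly entirely
    over the ring while crossing it.
    """

    center: tuple[float, float]  # (x, y)
    radius_px: float
    thickness_px: float = 12.0
    level: float = 0.35


@dataclass
class BlobSpec:
    """A moving dark translucent disc.

    ``path`` is an (n_frames, 2) array of (x, y) centers. ``contrast`` is
    the intensity depth below the *plain background* (dyed ≈ 0.4, undyed ≈
    0.05). The blob absorbs transmitted light, so over darker scenery it
    darkens proportionally: the pixels behind it are multiplied by
    (1 - contrast / background_level). Radius 4 px gives an area of
    ~50 px, inside the default prune window (2, 100).
    """

    path: np.ndarray
    radius_px: float = 4.0
    contrast: float = 0.4


@dataclass
class FlickerSpec:
    """Global multiplicative gain oscillation with a slow beat.

    The light output oscillates at twice the mains frequency
    (2 x 60 Hz); the camera clock (nominally ``capture_hz``) never matches
    it exactly, so the ``detune_hz`` mismatch aliases into a slow
    whole-field brightness beat across the recorded frames. Evaluating
    the light waveform at the true frame times reproduces exactly that
    beat (0.1 Hz by default, i.e. a 37.5-frame period at 3.75 fps).
    """

    amplitude: float = 0.03
    source_hz: float = 60.0
    capture_hz: float = 30.0
    detune_hz: float = 0.1

    def gain(self, n_frames: int, fps: float = DEFAULT_FPS) -> np.ndarray:
        t = np.arange(n_frames, dtype=np.float64) / fps
        phase = 2.0 * math.pi * (2.0 * self.source_hz + self.detune_hz)
        return 1.0 + self.amplitude * np.sin(phase * t)


@dataclass
class SynthScene:
    """Parametric description of a synthetic movie; ``seed`` fully
    determines the rendered output."""

    width: int = 640
    height: int = 480
    n_frames: int = 100
    fps: float = DEFAULT_FPS
    mm_per_px: float = DEFAULT_MM_PER_PX
    background_level: float = 0.85
    ring: RingSpec | None = None
    blobs: list[BlobSpec] = field(default_factory=list)
    flicker: FlickerSpec | None = None
    noise_sd: float = 0.01
    seed: int = 0


@dataclass
class GroundTruth:
    """True trajectories and static pixels of a rendered scene."""

    paths: list[np.ndarray]  # per blob: (n_frames, 3) of (frame, x, y)
    static_pixels: np.ndarray  # boolean (height, width) mask

    def track(self, blob: int = 0) -> Track:
        pts = [(int(f), float(x), float(y)) for f, x, y in self.paths[blob]]
        return Track(track_id=blob, points=pts, active=False)


def _disc_mask(height: int, width: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:height, :width]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _annulus_mask(height: int, width: int, ring: RingSpec) -> np.ndarray:
    cx, cy = ring.center
    yy, xx = np.ogrid[:height, :width]
    rr = np.hypot(xx - cx, yy - cy)
    return np.abs(rr - ring.radius_px) <= ring.thickness_px / 2.0


def render(scene: SynthScene) -> tuple[Movie, GroundTruth]:
    """Render a scene into a movie plus its ground truth.

    frame_t = clip(gain_t · (background with ring and blobs painted in)
    + noise). Blobs are filled translucent discs: pixels behind a blob are
    multiplied by (1 - contrast/background_level), so over the plain
    background the blob sits exactly ``contrast`` below it, while over the
    darker ring it darkens the ring proportionally — a faint (undyed) blob
    becomes nearly invisible against the dish edge, a dark (dyed) one does
    not.
    """
    if scene.n_frames < 1:
        raise ParameterError("scene needs at least one frame")
    for blob in scene.blobs:
        if blob.radius_px <= 0:
            raise ParameterError(f"blob radius must be > 0, got {blob.radius_px}")
        if not 0.0 <= blob.contrast <= scene.background_level:
            raise ParameterError(
                f"blob contrast must lie in [0, background_level], got {blob.contrast}"
            )
        if len(blob.path) != scene.n_frames:
            raise ParameterError(
                f"blob path has {len(blob.path)} points for {scene.n_frames} frames"
            )
    if scene.ring is not None and scene.ring.radius_px <= 0:
        raise ParameterError("ring radius must be > 0")

    h, w = scene.height, scene.width
    base = np.full((h, w), scene.background_level, dtype=np.float64)
    if scene.ring is not None:
        static = _annulus_mask(h, w, scene.ring)
        base[static] = scene.ring.level
    else:
        static = np.zeros((h, w), dtype=bool)

    gain = (
        scene.flicker.gain(scene.n_frames, scene.fps)
        if scene.flicker is not None
        else np.ones(scene.n_frames)
    )
    rng = np.random.default_rng(scene.seed)

    frames = np.empty((scene.n_frames, h, w), dtype=np.float64)
    for t in range(scene.n_frames):
        img = base.copy()
        for blob in scene.blobs:
            x, y = blob.path[t]
            transmittance = 1.0 - blob.contrast / scene.background_level
            img[_disc_mask(h, w, x, y, blob.radius_px)] *= transmittance
        img *= gain[t]
        if scene.noise_sd > 0:
            img += rng.normal(0.0, scene.noise_sd, size=(h, w))
        frames[t] = np.clip(img, 0.0, 1.0)

    paths = [
        np.column_stack([np.arange(scene.n_frames), np.asarray(b.path, float)])
        for b in scene.blobs
    ]
    movie = Movie(frames, fps=scene.fps, mm_per_px=scene.mm_per_px,
                  source=f"synth(seed={scene.seed})")
    return movie, GroundTruth(paths=paths, static_pixels=static)


def random_walk_path(
    n_frames: int,
    speed_mm_s: float,
    fps: float = DEFAULT_FPS,
    mm_per_px: float = DEFAULT_MM_PER_PX,
    turn_sd_rad: float = 0.2,
    seed: int = 0,
    start: tuple[float, float] | None = None,
    width: int = 640,
    height: int = 480,
    margin_px: float = 10.0,
) -> np.ndarray:
    """Correlated random walk emulating a crawling larva.

    Constant step length speed/(fps·mm_per_px) px per frame with Gaussian
    heading increments (sd ``turn_sd_rad``); the path reflects off the
    arena edges at ``margin_px`` from the border. Returns (n_frames, 2)
    (x, y) positions.
    """
    if speed_mm_s < 0:
        raise ParameterError("speed must be >= 0")
    rng = np.random.default_rng(seed)
    step = speed_mm_s / (fps * mm_per_px)
    lo_x, hi_x = margin_px, width - 1 - margin_px
    lo_y, hi_y = margin_px, height - 1 - margin_px

    x, y = start if start is not None else (width / 2.0, height / 2.0)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    path = np.empty((n_frames, 2))
    path[0] = (x, y)
    for i in range(1, n_frames):
        if turn_sd_rad > 0:
            heading += rng.normal(0.0, turn_sd_rad)
        nx = x + step * math.cos(heading)
        ny = y + step * math.sin(heading)
        # reflect off arena walls, flipping the matching heading component
        if nx < lo_x or nx > hi_x:
            nx = min(max(2 * lo_x - nx if nx < lo_x else 2 * hi_x - nx, lo_x), hi_x)
            heading = math.pi - heading
        if ny < lo_y or ny > hi_y:
            ny = min(max(2 * lo_y - ny if ny < lo_y else 2 * hi_y - ny, lo_y), hi_y)
            heading = -heading
        x, y = nx, ny
        path[i] = (x, y)
    return path


def straight_path(
    n_frames: int,
    start: tuple[float, float],
    step_px: float,
    heading_rad: float = 0.0,
) -> np.ndarray:
    """Straight constant-velocity path: convenience for tests/scenarios."""
    t = np.arange(n_frames, dtype=np.float64)
    return np.column_stack([
        start[0] + step_px * math.cos(heading_rad) * t,
        start[1] + step_px * math.sin(heading_rad) * t,
    ])


def jittered_track(
    path: np.ndarray, jitter_sd_px: float, seed: int = 0, track_id: int = 0
) -> Track:
    """A track equal to ``path`` plus iid per-axis Gaussian centroid noise.

    Feeds smoothing/speed tests without the cost of rendering a movie.
    """
    if jitter_sd_px < 0:
        raise ParameterError("jitter_sd_px must be >= 0")
    path = np.asarray(path, dtype=np.float64)
    rng = np.random.default_rng(seed)
    noisy = path + rng.normal(0.0, jitter_sd_px, size=path.shape)
    pts = [(i, float(x), float(y)) for i, (x, y) in enumerate(noisy)]
    return Track(track_id=track_id, points=pts, active=False)


def edge_crossing_scene(
    contrast: float = 0.4,
    n_frames: int = 80,
    width: int = 640,
    height: int = 480,
    seed: int = 0,
    speed_mm_s: float = 0.76,
    flicker: bool = False,
) -> SynthScene:
    """The dish-edge scenario: a blob crawling straight across the static
    ring (the failure mode of plain thresholding near the arena edge).

    ``contrast=0.4`` is the dyed regime, ``0.05`` the undyed one. The path
    runs horizontally through the ring at mid-height, centered on the
    crossing so roughly half the frames lie on either side. Flicker is off
    by default so the scenario isolates the static-edge failure mode;
    pass ``flicker=True`` to add the illumination beat on top.
    """
    ring = RingSpec(center=(width / 2.0, height / 2.0), radius_px=min(width, height) / 3.0)
    step = speed_mm_s / (DEFAULT_FPS * DEFAULT_MM_PER_PX)
    cross_x = ring.center[0] - ring.radius_px  # left edge of the ring
    start = (cross_x - step * n_frames / 2.0, height / 2.0)
    path = straight_path(n_frames, start, step_px=step)
    return SynthScene(
        width=width,
        height=height,
        n_frames=n_frames,
        ring=ring,
        blobs=[BlobSpec(path=path, contrast=contrast)],
        flicker=FlickerSpec() if flicker else None,
        seed=seed,
    )
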