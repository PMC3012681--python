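"""FAST frame processing: Frame Averaging followed by Subtraction then
Thresholding.

Static scene content (dish edges, dust, illumination gradients) is removed
by subtracting each frame from the movie-wide mean frame; only pixels
darker than the time average survive, so a dark crawling larva stands out
against a residual that is essentially zero everywhere else. This lets the
binary threshold be set very low (default 0.028) without picking up static
objects, in contrast to thresholding the raw images where the cutoff must
trade sensitivity against edge noise.

Also provided: the plain binary-threshold baseline, connected-component
labeling with centroids, and size pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from skimage import measure

from .errors import (
    DegenerateFrameError,
    DimensionError,
    EmptyInputError,
    ParameterError,
)
from .io_video import Movie

Method = Literal["fast", "baseline"]


@dataclass
class Cluster:
    """One connected pixel cluster surviving the threshold.

    ``centroid`` is the unweighted mean of the member pixel coordinates,
    as (x, y) = (column, row); ``pixel_count`` is the cluster area.
    """

    label: int
    pixel_count: int
    centroid: tuple[float, float]
    frame_index: int = 0


@dataclass
class PipelineConfig:
    """All numeric constants of the tracking method.

    Defaults follow the published pipeline: FAST threshold 0.028, cluster
    size bounds 2..100 px (inclusive), linking cutoff 10 px (~3 mm at
    0.3 mm/px). ``baseline_threshold`` is scene-dependent by nature (the
    weakness the FAST method removes) and defaults to 0.2, which separates
    a dark blob from a light background on typical synthetic scenes.
    """

    fast_threshold: float = 0.028
    baseline_threshold: float = 0.2
    min_cluster_px: int = 2
    max_cluster_px: int = 100
    link_max_px: float = 10.0
    connectivity: int = 8
    smoothing_sigma_frames: float = 1.0
    flicker_normalize: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.fast_threshold < 1.0:
            raise ParameterError(
                f"fast_threshold must lie in (0,1), got {self.fast_threshold}"
            )
        if not 0.0 < self.baseline_threshold < 1.0:
            raise ParameterError(
                f"baseline_threshold must lie in (0,1), got {self.baseline_threshold}"
            )
        if not 1 <= self.min_cluster_px <= self.max_cluster_px:
            raise ParameterError(
                "need 1 <= min_cluster_px <= max_cluster_px, got "
                f"({self.min_cluster_px}, {self.max_cluster_px})"
            )
        if self.link_max_px <= 0:
            raise ParameterError(f"link_max_px must be > 0, got {self.link_max_px}")
        if self.connectivity not in (4, 8):
            raise ParameterError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.smoothing_sigma_frames < 0:
            raise ParameterError("smoothing_sigma_frames must be >= 0")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_file(self, path: str | Path) -> None:
        """Write as key=value lines."""
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a key=value config file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParameterError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ParameterError(f"{path}:{lineno}: unknown key {key!r}")
                if key in ("min_cluster_px", "max_cluster_px", "connectivity"):
                    kwargs[key] = int(value)
                elif key == "flicker_normalize":
                    kwargs[key] = value.lower() in ("1", "true", "yes", "on")
                else:
                    kwargs[key] = float(value)
        return cls(**kwargs)


def average_frame(movie: Movie) -> np.ndarray:
    """Pixelwise arithmetic mean over all frames of the movie."""
    if movie.n_frames == 0:
        raise EmptyInputError("cannot average an empty movie")
    return movie.frames.mean(axis=0)


def subtract(mean: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """Dark-object residual: max(mean - frame, 0), pixelwise.

    Pixels darker than the time average (the larva) give a positive
    residual; static content cancels and brighter-than-average pixels are
    clipped to zero, since only darker-than-background objects are tracked.
    """
    mean = np.asarray(mean, dtype=np.float64)
    frame = np.asarray(frame, dtype=np.float64)
    if mean.shape != frame.shape:
        raise DimensionError(
            f"mean shape {mean.shape} != frame shape {frame.shape}"
        )
    return np.clip(mean - frame, 0.0, 1.0)


def threshold_mask(residual: np.ndarray, t: float) -> np.ndarray:
    """Binary mask of pixels whose residual strictly exceeds ``t``."""
    if not 0.0 < t < 1.0:
        raise ParameterError(f"threshold must lie in (0,1), got {t}")
    return np.asarray(residual) > t


def baseline_mask(frame: np.ndarray, t: float) -> np.ndarray:
    """Plain binary threshold on the raw frame: dark pixels with
    (1 - intensity) > t, with no background subtraction.

    This is the conventional approach FAST improves on: the cutoff has to
    be chosen per movie, and any static dark object (dish edge) passes it
    together with the larva.
    """
    if not 0.0 < t < 1.0:
        raise ParameterError(f"threshold must lie in (0,1), got {t}")
    return (1.0 - np.asarray(frame)) > t


def flicker_normalize(movie: Movie) -> Movie:
    """Rescale every frame to the mean of the per-frame means.

    Removes global illumination flicker (the beat between mains-driven
    light output and the camera clock) before subtraction: each frame is
    multiplied by (mean of frame means) / (its own mean) and clipped to
    [0, 1].
    """
    if movie.n_frames == 0:
        raise EmptyInputError("cannot normalize an empty movie")
    frame_means = movie.frames.mean(axis=(1, 2))
    if np.any(frame_means == 0.0):
        bad = int(np.argmax(frame_means == 0.0))
        raise DegenerateFrameError(f"frame {bad} has zero mean intensity")
    gain = frame_means.mean() / frame_means
    frames = np.clip(movie.frames * gain[:, None, None], 0.0, 1.0)
    return Movie(frames, fps=movie.fps, mm_per_px=movie.mm_per_px,
                 source=movie.source)


def label_clusters(
    mask: np.ndarray, connectivity: int = 8, frame_index: int = 0
) -> list[Cluster]:
    """Partition the true pixels of ``mask`` into maximal connected
    components (4- or 8-adjacency) and return one :class:`Cluster` per
    component with its area and unweighted centroid."""
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    # skimage connectivity: 1 = edges only (4-adjacency), 2 = + diagonals
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    clusters = []
    for region in measure.regionprops(labels):
        cy, cx = region.centroid  # (row, col) -> (y, x)
        clusters.append(
            Cluster(
                label=int(region.label),
                pixel_count=int(region.area),
                centroid=(float(cx), float(cy)),
                frame_index=frame_index,
            )
        )
    return clusters


def prune_clusters(
    clusters: Sequence[Cluster], min_px: int, max_px: int
) -> list[Cluster]:
    """Keep clusters with min_px <= pixel_count <= max_px (bounds inclusive).

    Removes single-pixel speckle noise below ``min_px`` and oversized
    static artifacts (or larva-plus-edge merges) above ``max_px``.
    """
    if min_px > max_px:
        raise ParameterError(f"min_px {min_px} > max_px {max_px}")
    return [c for c in clusters if min_px <= c.pixel_count <= max_px]


def detect(
    movie: Movie, config: PipelineConfig, method: Method = "fast"
) -> list[list[Cluster]]:
    """Run the full per-frame detection pipeline.

    ``method="fast"``: (optional flicker normalization) → mean frame →
    per-frame dark residual → threshold at ``fast_threshold`` → label →
    size-prune. ``method="baseline"``: per-frame dark threshold at
    ``baseline_threshold`` → label → size-prune, with no background
    subtraction.

    Returns one list of pruned clusters per frame.
    """
    if movie.n_frames == 0:
        raise EmptyInputError("cannot run detection on an empty movie")
    if method not in ("fast", "baseline"):
        raise ParameterError(f"unknown method {method!r}")

    if method == "fast":
        if config.flicker_normalize:
            movie = flicker_normalize(movie)
        mean = average_frame(movie)

    detections: list[list[Cluster]] = []
    for i, frame in enumerate(movie.frames):
        if method == "fast":
            mask = threshold_mask(subtract(mean, frame), config.fast_threshold)
        else:
            mask = baseline_mask(frame, config.baseline_threshold)
        clusters = label_clusters(mask, config.connectivity, frame_index=i)
        detections.append(
            prune_clusters(clusters, config.min_cluster_px, config.max_cluster_px)
        )
    return detections
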