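"""Nearest-center track linking.

Per-frame blob centroids are joined into tracks by comparing each frame's
centers with the active track heads from the previous frame: all
(head, detection) pairs are sorted by Euclidean distance and accepted
greedily, nearest first, provided the distance is strictly below the
linking cutoff (default 10 px, ~3 mm). Unmatched detections start new
tracks; a track with no match is terminated — there is no gap bridging and
no attempt to preserve identities through track intersections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .fast_core import Cluster
from .io_video import TrackTable


@dataclass
class Track:
    """One object's time-ordered centroid sequence.

    ``points`` holds (frame_index, x, y) with consecutive frame indices;
    ``active`` marks tracks still eligible for extension during assembly.
    """

    track_id: int
    points: list[tuple[int, float, float]] = field(default_factory=list)
    active: bool = True

    def __len__(self) -> int:
        return len(self.points)

    @property
    def head(self) -> tuple[float, float]:
        _, x, y = self.points[-1]
        return (x, y)

    @property
    def frames(self) -> list[int]:
        return [p[0] for p in self.points]


@dataclass
class TrackSet:
    """All tracks from one linking run plus the cutoff used."""

    tracks: list[Track]
    link_max_px: float

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def to_table(self, fps: float, mm_per_px: float) -> TrackTable:
        rows = [
            (t.track_id, f, x, y)
            for t in self.tracks
            for (f, x, y) in t.points
        ]
        df = pd.DataFrame(rows, columns=["track_id", "frame_index", "x_px", "y_px"])
        return TrackTable(df, fps=fps, mm_per_px=mm_per_px)

    @staticmethod
    def from_table(table: TrackTable) -> "TrackSet":
        tracks = []
        for tid, group in table.data.groupby("track_id", sort=True):
            group = group.sort_values("frame_index")
            pts = [
                (int(f), float(x), float(y))
                for f, x, y in zip(group["frame_index"], group["x_px"], group["y_px"])
            ]
            tracks.append(Track(int(tid), pts, active=False))
        return TrackSet(tracks, link_max_px=float("nan"))


def link(
    detections: Sequence[Sequence[Cluster]], link_max_px: float = 10.0
) -> TrackSet:
    """Link per-frame detections into tracks by greedy nearest-first
    matching with a strict distance cutoff.

    Within each frame every pair of (active track head, detection) with
    distance < ``link_max_px`` is a candidate; candidates are accepted in
    order of increasing distance (ties broken by lower track id, then lower
    detection index), each head and each detection used at most once.
    """
    if link_max_px <= 0:
        raise ParameterError(f"link_max_px must be > 0, got {link_max_px}")

    tracks: list[Track] = []
    active: list[Track] = []

    for frame_idx, frame_dets in enumerate(detections):
        centers = [c.centroid for c in frame_dets]

        # candidate pairs under the cutoff, nearest first, deterministic ties
        candidates = []
        for track in active:
            hx, hy = track.head
            for j, (x, y) in enumerate(centers):
                d = math.hypot(x - hx, y - hy)
                if d < link_max_px:
                    candidates.append((d, track.track_id, j, track))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))

        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        for d, tid, j, track in candidates:
            if tid in matched_tracks or j in matched_dets:
                continue
            x, y = centers[j]
            track.points.append((frame_idx, x, y))
            matched_tracks.add(tid)
            matched_dets.add(j)

        # unmatched active tracks terminate (no gap bridging)
        still_active = []
        for track in active:
            if track.track_id in matched_tracks:
                still_active.append(track)
            else:
                track.active = False
        active = still_active

        # unmatched detections seed new tracks
        for j, (x, y) in enumerate(centers):
            if j not in matched_dets:
                t = Track(track_id=len(tracks), points=[(frame_idx, x, y)])
                tracks.append(t)
                active.append(t)

    for t in tracks:
        t.active = False
    return TrackSet(tracks, link_max_px=link_max_px)


def track_durations(tracks: TrackSet, fps: float) -> list[float]:
    """Duration of each track in seconds: (n_points - 1) / fps."""
    if fps <= 0:
        raise ParameterError(f"fps must be > 0, got {fps}")
    return [(len(t) - 1) / fps for t in tracks]


def track_completeness(
    tracks: TrackSet,
    truth: Sequence[tuple[int, float, float]],
    tol_px: float = 5.0,
) -> float:
    """Fraction of ground-truth frames covered by the single best track.

    A truth point (frame, x, y) counts as covered when the track has a
    point at that frame within ``tol_px``. This is the success criterion
    for tracking near arena edges: a complete track covers every frame the
    animal is present.
    """
    if not truth:
        return 0.0
    best = 0
    for track in tracks:
        by_frame = {f: (x, y) for f, x, y in track.points}
        n = 0
        for f, tx, ty in truth:
            p = by_frame.get(f)
            if p is not None and math.hypot(p[0] - tx, p[1] - ty) <= tol_px:
                n += 1
        best = max(best, n)
    return best / len(truth)
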