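"""Movie and track-table I/O.

Movies are ordered stacks of grayscale frames normalized to [0, 1]
(0 = black, 1 = white; larvae are dark objects on a light background,
matching a transmitted-light rig). Coordinates are 0-based with
x = column, y = row and pixel centers at integer coordinates.

Supported movie containers: multi-page TIFF, a directory of
lexicographically ordered PNG/TIFF frames, and AVI when an
ffmpeg-capable imageio backend is installed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, EmptyInputError, FormatError, ParseError

#: Acquisition defaults: 3.75 frames per second and 10 px ~ 3 mm.
DEFAULT_FPS = 3.75
DEFAULT_MM_PER_PX = 0.3

_FRAME_EXTENSIONS = {".png", ".tif", ".tiff"}
_VIDEO_EXTENSIONS = {".avi", ".mp4", ".mov"}

TRACK_COLUMNS = ["track_id", "frame_index", "x_px", "y_px"]
TRACK_UNIT_COLUMNS = ["x_mm", "y_mm", "time_s"]


@dataclass
class Movie:
    """A grayscale movie plus its acquisition metadata.

    ``frames`` is an (n_frames, height, width) float array with values in
    [0, 1]; ``fps`` and ``mm_per_px`` carry the temporal and spatial scale.
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS
    mm_per_px: float = DEFAULT_MM_PER_PX
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise DimensionError(
                f"frames must be a (n, h, w) stack, got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.mm_per_px <= 0:
            raise ValueError(f"mm_per_px must be positive, got {self.mm_per_px}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        return iter(self.frames)


@dataclass
class TrackTable:
    """Tabular track export: one row per (track_id, frame_index) point."""

    data: pd.DataFrame
    fps: float = DEFAULT_FPS
    mm_per_px: float = DEFAULT_MM_PER_PX

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")

    def with_units(self) -> "TrackTable":
        """Return a copy with x_mm, y_mm and time_s columns filled in."""
        df = self.data.copy()
        df["x_mm"] = df["x_px"] * self.mm_per_px
        df["y_mm"] = df["y_px"] * self.mm_per_px
        df["time_s"] = df["frame_index"] / self.fps
        return TrackTable(df, self.fps, self.mm_per_px)


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    # Monochrome camera convention: color inputs are channel-averaged.
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2-D frame, got shape {arr.shape}")
    return arr


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Affine rescale from native bit depth to [0, 1] (rank-preserving)."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return (arr.astype(np.float64) - info.min) / (info.max - info.min)
    # float input is assumed pre-normalized
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _stack_frames(raw_frames: Sequence[np.ndarray], source: str) -> np.ndarray:
    if len(raw_frames) == 0:
        raise EmptyInputError(f"no frames found in {source!r}")
    frames = [_to_grayscale(_normalize(np.asarray(f))) for f in raw_frames]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise DimensionError(f"mixed frame sizes in {source!r}: {sorted(shapes)}")
    return np.stack(frames)


def _read_avi(path: Path) -> list[np.ndarray]:
    import imageio.v2 as imageio

    try:
        reader = imageio.get_reader(str(path))
    except Exception as exc:  # missing ffmpeg backend or corrupt file
        raise FormatError(
            f"cannot decode {path}: {exc}. Reading AVI requires an "
            "ffmpeg-capable imageio backend (imageio-ffmpeg)."
        ) from exc
    with reader:
        return [np.asarray(frame) for frame in reader]


def load_movie(
    path: str | Path,
    fps: float = DEFAULT_FPS,
    mm_per_px: float = DEFAULT_MM_PER_PX,
) -> Movie:
    """Load a movie from an AVI, a multi-page TIFF, or a frame directory.

    Pixel intensities are rescaled from the native bit depth to [0, 1];
    frame order is the file/page order (directory entries are sorted
    lexicographically).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such movie source: {path}")

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not files:
            raise EmptyInputError(f"directory {path} contains no PNG/TIFF frames")
        import imageio.v2 as imageio

        try:
            raw = [imageio.imread(f) for f in files]
        except Exception as exc:
            raise FormatError(f"cannot read frame files in {path}: {exc}") from exc
        frames = _stack_frames(raw, str(path))
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        try:
            arr = tifffile.imread(str(path))
        except Exception as exc:
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        frames = _stack_frames(list(arr), str(path))
    elif path.suffix.lower() in _VIDEO_EXTENSIONS:
        frames = _stack_frames(_read_avi(path), str(path))
    else:
        raise FormatError(f"unsupported movie format: {path.suffix!r} ({path})")

    return Movie(frames, fps=fps, mm_per_px=mm_per_px, source=str(path))


def save_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as 8-bit frames (multi-page TIFF, frame directory or AVI).

    Quantization to the 8-bit grid is the only loss; save→load round-trips
    with a pixelwise error of at most 1/255.
    """
    if movie.n_frames == 0:
        raise EmptyInputError("cannot save an empty movie")
    path = Path(path)
    frames_u8 = np.clip(np.rint(movie.frames * 255.0), 0, 255).astype(np.uint8)

    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), frames_u8, photometric="minisblack")
    elif path.suffix.lower() in _VIDEO_EXTENSIONS:
        import imageio.v2 as imageio

        try:
            imageio.mimwrite(str(path), list(frames_u8), fps=movie.fps)
        except Exception as exc:
            raise FormatError(
                f"cannot encode {path}: {exc}. Writing AVI requires an "
                "ffmpeg-capable imageio backend (imageio-ffmpeg)."
            ) from exc
    else:
        # treat as a directory of PNG frames
        import imageio.v2 as imageio

        path.mkdir(parents=True, exist_ok=True)
        ndigits = max(4, len(str(movie.n_frames - 1)))
        for i, frame in enumerate(frames_u8):
            imageio.imwrite(path / f"frame_{i:0{ndigits}d}.png", frame)


def write_tracks(tracks: TrackTable, path: str | Path) -> None:
    """Write a track table as CSV with '#'-prefixed metadata lines."""
    path = Path(path)
    cols = TRACK_COLUMNS + [c for c in TRACK_UNIT_COLUMNS if c in tracks.data.columns]
    with open(path, "w", newline="") as fh:
        fh.write(f"# fps={tracks.fps}\n")
        fh.write(f"# mm_per_px={tracks.mm_per_px}\n")
        fh.write(",".join(cols) + "\n")
        writer = csv.writer(fh)
        for row in tracks.data[cols].itertuples(index=False):
            writer.writerow(list(row))


def read_tracks(path: str | Path) -> TrackTable:
    """Read a track CSV written by :func:`write_tracks`.

    Raises :class:`ParseError` with the offending 1-based line number on
    malformed input.
    """
    path = Path(path)
    fps = DEFAULT_FPS
    mm_per_px = DEFAULT_MM_PER_PX
    header: list[str] | None = None
    rows: list[list[float]] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key = key.strip()
                    try:
                        if key == "fps":
                            fps = float(value)
                        elif key == "mm_per_px":
                            mm_per_px = float(value)
                    except ValueError as exc:
                        raise ParseError(f"bad metadata value {value!r}", lineno) from exc
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in TRACK_COLUMNS if c not in header]
                if missing:
                    raise ParseError(f"missing columns {missing}", lineno)
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(fields)}", lineno
                )
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise ParseError(f"non-numeric field in {fields!r}", lineno) from exc
            rows.append(values)

    if header is None:
        raise ParseError("no header line found", None)

    df = pd.DataFrame(rows, columns=header)
    for col in ("track_id", "frame_index"):
        df[col] = df[col].astype(int)
    return TrackTable(df, fps=fps, mm_per_px=mm_per_px)
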