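"""Decode, standardize and sample cone-assay videos.

Assay footage is standardized to the analysis format — 540 x 960 px,
30 frames/s, single channel — before anything downstream touches it.  The
package's native container is multi-page TIFF (lossless, frame rate carried
in the TIFF description), which any scientific image reader can open.  When
an ``ffmpeg`` executable is available on PATH, MPEG-4/H.264 files can be read
and written as well (H.264 at ~1500 kb/s, the usual smartphone delivery
format); without it the TIFF path covers the whole pipeline.
"""

from __future__ import annotations

import json
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile

STANDARD_WIDTH = 540
STANDARD_HEIGHT = 960
STANDARD_FPS = 30.0
STANDARD_BITRATE_KBPS = 1500

#: luma weights for RGB -> intensity conversion (ITU-R BT.601)
_LUMA = np.array([0.299, 0.587, 0.114], dtype=np.float32)

_TIFF_SUFFIXES = {".tif", ".tiff"}


class VideoDecodeError(RuntimeError):
    """Raised when a file cannot be opened or decoded as video."""


class EmptyVideoError(VideoDecodeError):
    """Raised when a video contains no frames."""


@dataclass(frozen=True)
class VideoAsset:
    """Descriptor of a decodable video file."""

    source_path: Path
    width: int
    height: int
    fps: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def duration(self) -> float:
        """Video duration in seconds (n_frames / fps)."""
        return self.n_frames / self.fps

    @property
    def is_standard(self) -> bool:
        return (
            self.width == STANDARD_WIDTH
            and self.height == STANDARD_HEIGHT
            and abs(self.fps - STANDARD_FPS) < 1e-6
        )


@dataclass(frozen=True)
class TimedFrame:
    """A single sampled frame with its timestamp.

    ``t`` is derived from frame index / fps rather than container timestamps,
    so sampling is deterministic across decoders.  ``valid`` is False when the
    frame could not be decoded; invalid frames carry a zero image and are
    excluded from activity accounting downstream.
    """

    t: float
    pixels: np.ndarray
    index: int
    valid: bool = True


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an (H, W[, 3]) uint8 frame to single-channel uint8 intensity."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return (frame[..., :3].astype(np.float32) @ _LUMA).clip(0, 255).astype(np.uint8)
    raise ValueError(f"unsupported frame shape {frame.shape}")


# ---------------------------------------------------------------------------
# readers / writers


class TiffVideoReader:
    """Random-access reader for multi-page TIFF video."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        try:
            self._tif = tifffile.TiffFile(self.path)
        except (OSError, ValueError, tifffile.TiffFileError) as exc:
            raise VideoDecodeError(f"cannot decode {self.path}: {exc}") from exc
        series = self._tif.series
        if not series or series[0].shape[0] == 0:
            self._tif.close()
            raise EmptyVideoError(f"{self.path} contains no frames")
        self._series = series[0]
        self.fps = self._read_fps()
        shape = self._series.shape
        if len(shape) == 2:  # single page
            self.n_frames = 1
            self.height, self.width = shape
        else:
            self.n_frames = shape[0]
            self.height, self.width = shape[1], shape[2]
        self._data = None
        try:  # contiguous uncompressed series memory-map for fast sampling
            self._data = tifffile.memmap(self.path)
            if self._data.ndim == 2:
                self._data = self._data[None]
        except ValueError:
            pass

    def _read_fps(self) -> float:
        desc = self._tif.pages[0].description or ""
        try:
            return float(json.loads(desc)["fps"])
        except (ValueError, KeyError, TypeError):
            return STANDARD_FPS

    def asset(self) -> VideoAsset:
        return VideoAsset(self.path, self.width, self.height, self.fps, self.n_frames)

    def read(self, index: int) -> np.ndarray:
        if not 0 <= index < self.n_frames:
            raise IndexError(index)
        if self._data is not None:
            return np.asarray(self._data[index])
        if len(self._series.shape) == 2:
            return self._tif.pages[0].asarray()
        return self._tif.pages[index].asarray()

    def close(self) -> None:
        self._tif.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class TiffVideoWriter:
    """Appends uint8 frames to a multi-page TIFF, recording fps in metadata."""

    def __init__(self, path: str | Path, fps: float):
        self.path = Path(path)
        self.fps = float(fps)
        self._writer = tifffile.TiffWriter(self.path, bigtiff=True)
        self.n_written = 0

    def append(self, frame: np.ndarray) -> None:
        frame = np.ascontiguousarray(frame, dtype=np.uint8)
        desc = json.dumps({"fps": self.fps}) if self.n_written == 0 else None
        self._writer.write(
            frame, contiguous=True, description=desc, photometric="minisblack"
        )
        self.n_written += 1

    def close(self) -> None:
        self._writer.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def ffmpeg_available() -> bool:
    return shutil.which("ffmpeg") is not None and shutil.which("ffprobe") is not None


class FfmpegVideoReader:
    """Sequential reader for containers decoded by an external ffmpeg."""

    def __init__(self, path: str | Path):
        if not ffmpeg_available():
            raise VideoDecodeError(
                f"{path}: no ffmpeg on PATH; only TIFF video is supported here"
            )
        self.path = Path(path)
        probe = subprocess.run(
            [
                "ffprobe", "-v", "error", "-select_streams", "v:0",
                "-show_entries", "stream=width,height,r_frame_rate,nb_read_frames",
                "-count_frames", "-of", "json", str(self.path),
            ],
            capture_output=True,
            text=True,
        )
        if probe.returncode != 0:
            raise VideoDecodeError(f"cannot decode {self.path}: {probe.stderr.strip()}")
        info = json.loads(probe.stdout)["streams"][0]
        num, den = info["r_frame_rate"].split("/")
        self.fps = float(num) / float(den)
        self.width = int(info["width"])
        self.height = int(info["height"])
        self.n_frames = int(info["nb_read_frames"])
        if self.n_frames == 0:
            raise EmptyVideoError(f"{self.path} contains no frames")
        self._frames: np.ndarray | None = None

    def _decode_all(self) -> np.ndarray:
        proc = subprocess.run(
            [
                "ffmpeg", "-v", "error", "-i", str(self.path),
                "-f", "rawvideo", "-pix_fmt", "gray", "-",
            ],
            capture_output=True,
        )
        if proc.returncode != 0:
            raise VideoDecodeError(proc.stderr.decode(errors="replace"))
        buf = np.frombuffer(proc.stdout, dtype=np.uint8)
        return buf.reshape(-1, self.height, self.width)

    def asset(self) -> VideoAsset:
        return VideoAsset(self.path, self.width, self.height, self.fps, self.n_frames)

    def read(self, index: int) -> np.ndarray:
        if self._frames is None:
            self._frames = self._decode_all()
        return self._frames[index]

    def close(self) -> None:
        self._frames = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def open_video(path: str | Path):
    """Open a video file with the appropriate reader (TIFF native, else ffmpeg)."""
    path = Path(path)
    if not path.exists():
        raise VideoDecodeError(f"no such file: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return TiffVideoReader(path)
    return FfmpegVideoReader(path)


def open_writer(path: str | Path, fps: float):
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return TiffVideoWriter(path, fps)
    if ffmpeg_available():
        return _FfmpegVideoWriter(path, fps)
    raise VideoDecodeError(
        f"cannot write {path}: no ffmpeg on PATH; use a .tif extension"
    )


class _FfmpegVideoWriter:
    """Pipes gray frames to ffmpeg for H.264-in-MPEG-4 output."""

    def __init__(self, path: str | Path, fps: float, bitrate_kbps: int = STANDARD_BITRATE_KBPS):
        self.path = Path(path)
        self.fps = float(fps)
        self._proc = None
        self._bitrate = bitrate_kbps
        self.n_written = 0

    def _start(self, height: int, width: int) -> None:
        self._proc = subprocess.Popen(
            [
                "ffmpeg", "-v", "error", "-y",
                "-f", "rawvideo", "-pix_fmt", "gray",
                "-s", f"{width}x{height}", "-r", f"{self.fps}",
                "-i", "-",
                "-c:v", "libx264", "-b:v", f"{self._bitrate}k",
                "-pix_fmt", "yuv420p", str(self.path),
            ],
            stdin=subprocess.PIPE,
        )

    def append(self, frame: np.ndarray) -> None:
        frame = np.ascontiguousarray(frame, dtype=np.uint8)
        if self._proc is None:
            self._start(*frame.shape)
        self._proc.stdin.write(frame.tobytes())
        self.n_written += 1

    def close(self) -> None:
        if self._proc is not None:
            self._proc.stdin.close()
            self._proc.wait()
            self._proc = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


# ---------------------------------------------------------------------------
# standardization


def _resize_gray(frame: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Resize a single-channel frame; fast box-mean path for integer downscale."""
    in_h, in_w = frame.shape
    if in_h == out_h and in_w == out_w:
        return frame
    if in_h % out_h == 0 and in_w % out_w == 0 and in_h // out_h == in_w // out_w:
        f = in_h // out_h
        return (
            frame.reshape(out_h, f, out_w, f)
            .mean(axis=(1, 3))
            .round()
            .clip(0, 255)
            .astype(np.uint8)
        )
    from skimage.transform import resize

    out = resize(frame, (out_h, out_w), order=1, anti_aliasing=in_h > out_h,
                 preserve_range=True)
    return out.round().clip(0, 255).astype(np.uint8)


def letterbox(frame: np.ndarray, out_w: int = STANDARD_WIDTH,
              out_h: int = STANDARD_HEIGHT) -> np.ndarray:
    """Scale to fit and centre-pad with black, preserving aspect ratio.

    Distortion would shift the cone geometry used for region assignment, so
    aspect mismatches are letterboxed rather than stretched.
    """
    in_h, in_w = frame.shape
    scale = min(out_w / in_w, out_h / in_h)
    new_w = max(1, round(in_w * scale))
    new_h = max(1, round(in_h * scale))
    resized = _resize_gray(frame, new_h, new_w)
    if new_w == out_w and new_h == out_h:
        return resized
    canvas = np.zeros((out_h, out_w), dtype=np.uint8)
    y0 = (out_h - new_h) // 2
    x0 = (out_w - new_w) // 2
    canvas[y0 : y0 + new_h, x0 : x0 + new_w] = resized
    return canvas


def standardize_video(
    raw_path: str | Path,
    out_path: str | Path,
    *,
    width: int = STANDARD_WIDTH,
    height: int = STANDARD_HEIGHT,
    fps: float = STANDARD_FPS,
) -> VideoAsset:
    """Convert any decodable video to the analysis format.

    Frames are converted to intensity, letterboxed to ``width`` x ``height``
    and resampled to ``fps`` by nearest-frame index mapping.  Returns a
    :class:`VideoAsset` describing the written file.
    """
    with open_video(raw_path) as reader:
        if reader.n_frames == 0:
            raise EmptyVideoError(f"{raw_path} contains no frames")
        n_out = max(1, round(reader.n_frames * fps / reader.fps))
        with open_writer(out_path, fps) as writer:
            for k in range(n_out):
                src = min(reader.n_frames - 1, round(k * reader.fps / fps))
                frame = to_grayscale(reader.read(src))
                writer.append(letterbox(frame, width, height))
    return VideoAsset(Path(out_path), width, height, fps, n_out)


def probe_video(path: str | Path) -> VideoAsset:
    """Return the :class:`VideoAsset` descriptor of an existing file."""
    with open_video(path) as reader:
        return reader.asset()


# ---------------------------------------------------------------------------
# sampling


def sample_indices(n_frames: int, fps: float, interval: float) -> list[int]:
    """Frame indices nearest to t = 0, interval, 2*interval, ...

    Count is floor(duration / interval) + 1, capped at the available frames;
    at 30 fps and the analysis interval of 0.1 s this is every 3rd frame.
    """
    if interval < 1.0 / fps:
        raise ValueError("interval must be at least one frame period")
    duration = n_frames / fps
    n_samples = int(np.floor(duration / interval + 1e-9)) + 1
    out = []
    for k in range(n_samples):
        idx = round(k * interval * fps)
        if idx >= n_frames:
            break
        out.append(idx)
    return out


def sample_frames(
    asset: VideoAsset | str | Path, interval: float = 0.1
) -> Iterator[TimedFrame]:
    """Yield grayscale :class:`TimedFrame` samples at the given interval.

    Frames that fail to decode mid-stream are yielded with ``valid=False`` and
    a zero image so downstream valid-frame accounting can see them.
    """
    path = asset.source_path if isinstance(asset, VideoAsset) else Path(asset)
    with open_video(path) as reader:
        shape = (reader.height, reader.width)
        for index in sample_indices(reader.n_frames, reader.fps, interval):
            t = index / reader.fps
            try:
                frame = to_grayscale(reader.read(index))
            except (VideoDecodeError, OSError, ValueError):
                yield TimedFrame(t, np.zeros(shape, np.uint8), index, valid=False)
            else:
                yield TimedFrame(t, frame, index, valid=True)
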