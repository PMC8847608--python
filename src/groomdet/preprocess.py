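"""Video -> binary differential frames -> grouped network inputs.

Pipeline per differential frame (time ``t`` indexes the diff between raw
frames ``t`` and ``t+1``; the *later* frame supplies both the label and the
crop center):

    abs diff -> crop around mouse centroid -> resize -> grayscale -> binarize

Grayscale uses the standard luma weights (0.299, 0.587, 0.114), fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .labels import LabelTrack, as_track

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = {".png", ".bmp", ".jpg", ".jpeg", ".pgm", ".ppm", ".tif", ".tiff"}


class EmptyVideoError(ValueError):
    """Raised when a video source yields no frames."""


class CentroidNotFoundError(ValueError):
    """Raised when no foreground pixel survives thresholding and no fallback exists."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the crop/resize/binarize pipeline.

    ``binarize_threshold`` and ``centroid_threshold`` are 8-bit intensity
    cuts (a pixel >= threshold is foreground).  ``foreground_polarity``
    selects whether the animal is brighter ("bright") or darker ("dark")
    than the arena.
    """

    crop_side: int = 256
    out_side: int = 128
    binarize_threshold: int = 20
    centroid_threshold: int = 128
    foreground_polarity: str = "bright"

    def __post_init__(self) -> None:
        if self.crop_side <= 0 or self.out_side <= 0:
            raise ValueError("crop_side and out_side must be positive")
        if not 1 <= self.binarize_threshold <= 255:
            raise ValueError("binarize_threshold must be in [1, 255]")
        if not 1 <= self.centroid_threshold <= 255:
            raise ValueError("centroid_threshold must be in [1, 255]")
        if self.foreground_polarity not in ("bright", "dark"):
            raise ValueError("foreground_polarity must be 'bright' or 'dark'")


@dataclass
class Video:
    """An in-memory frame sequence: (T, H, W) or (T, H, W, 3) uint8."""

    frames: np.ndarray
    fps: float = 60.0
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim not in (3, 4) or arr.shape[0] == 0:
            raise EmptyVideoError("video must contain at least one frame")
        self.frames = arr

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration(self) -> float:
        return len(self) / self.fps


def extract_frames(video_path: str | Path, fps: float = 60.0) -> Video:
    """Load a frame sequence from disk.

    Supported containers: a directory of image files (sorted by name), a
    multi-page TIFF, or a ``.npy`` array of shape (T, H, W[, 3]).
    """
    path = Path(video_path)
    if not path.exists():
        raise IOError(f"video source not found: {path}")
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise EmptyVideoError(f"no image frames in directory {path}")
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    elif path.suffix.lower() == ".npy":
        frames = np.load(path)
        if frames.ndim not in (3, 4) or frames.shape[0] == 0:
            raise EmptyVideoError(f"{path}: expected non-empty (T, H, W[, 3]) array")
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        raise IOError(
            f"unsupported video container {path.suffix!r}: use an image-sequence "
            "directory, a multi-page TIFF, or a .npy stack"
        )
    return Video(np.ascontiguousarray(frames), fps=fps, source_id=path.stem)


def abs_diff(frame_a: np.ndarray, frame_b: np.ndarray) -> np.ndarray:
    """Channel-wise absolute difference of two equally shaped frames."""
    a, b = np.asarray(frame_a), np.asarray(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shape mismatch: {a.shape} vs {b.shape}")
    return np.abs(a.astype(np.int16) - b.astype(np.int16)).astype(np.uint8)


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luma grayscale for 3-channel images; identity for single-channel."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        return arr @ LUMA_WEIGHTS
    if arr.ndim == 2:
        return arr
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got shape {arr.shape}")


def binarize(image: np.ndarray, threshold: int) -> np.ndarray:
    """Threshold a grayscale image to {0, 1}; idempotent for thresholds <= 1."""
    return (np.asarray(image) >= threshold).astype(np.uint8)


def mouse_centroid(frame: np.ndarray, config: PreprocessConfig) -> tuple[float, float]:
    """Centroid (row, col) of the largest 8-connected foreground component.

    The raw frame is grayscaled, optionally inverted (dark foreground), then
    thresholded at ``centroid_threshold``.
    """
    gray = to_gray(frame)
    if config.foreground_polarity == "dark":
        gray = 255.0 - gray
    mask = gray >= config.centroid_threshold
    if not mask.any():
        raise CentroidNotFoundError("no foreground pixel above centroid_threshold")
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    lab, n = ndimage.label(mask, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    r, c = ndimage.center_of_mass(mask, lab, largest)
    return float(r), float(c)


def crop_square(image: np.ndarray, center: tuple[float, float], side: int) -> np.ndarray:
    """Extract a ``side x side`` window centered at ``center``, zero-padded."""
    if side <= 0:
        raise ValueError("crop side must be positive")
    arr = np.asarray(image)
    r0 = int(round(center[0])) - side // 2
    c0 = int(round(center[1])) - side // 2
    out_shape = (side, side) + arr.shape[2:]
    out = np.zeros(out_shape, dtype=arr.dtype)
    rs, re = max(r0, 0), min(r0 + side, arr.shape[0])
    cs, ce = max(c0, 0), min(c0 + side, arr.shape[1])
    if rs < re and cs < ce:
        out[rs - r0:re - r0, cs - c0:ce - c0] = arr[rs:re, cs:ce]
    return out


def _resize(image: np.ndarray, side: int) -> np.ndarray:
    if image.shape[0] == side and image.shape[1] == side:
        return image.astype(np.float64)
    # anti-alias on downsampling so sparse motion pixels are averaged in,
    # not dropped by subsampling
    downsampling = side < image.shape[0]
    return _sk_resize(
        image, (side, side) + image.shape[2:], order=1,
        anti_aliasing=downsampling, preserve_range=True,
    )


@dataclass
class BinaryDiffStack:
    """Preprocessed per-video stack of binary differential frames."""

    frames: np.ndarray  # (T-1, S, S) uint8 in {0, 1}
    source_id: str = ""
    fps: float = 60.0
    config: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=np.uint8)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError("diff stack must be a non-empty (L, S, S) array")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("diff stack pixels must be binary")
        self.frames = arr

    def __len__(self) -> int:
        return int(self.frames.shape[0])


def preprocess_video(video: Video, config: PreprocessConfig | None = None) -> BinaryDiffStack:
    """Run the full diff/crop/resize/gray/binarize pipeline over a video.

    Diff frame ``t`` covers raw frames ``t``/``t+1`` and is cropped at the
    centroid of raw frame ``t+1``; when the centroid cannot be found the
    previous frame's centroid is reused.
    """
    config = config or PreprocessConfig()
    frames = video.frames
    if len(video) < 2:
        raise ValueError("need at least 2 frames to form differential images")
    out = np.empty((len(video) - 1, config.out_side, config.out_side), dtype=np.uint8)
    last_centroid: tuple[float, float] | None = None
    for t in range(len(video) - 1):
        diff = abs_diff(frames[t], frames[t + 1])
        try:
            last_centroid = mouse_centroid(frames[t + 1], config)
        except CentroidNotFoundError:
            if last_centroid is None:
                raise CentroidNotFoundError(
                    f"no mouse found in frame {t + 1} and no earlier centroid to fall back on"
                )
        cropped = crop_square(diff, last_centroid, config.crop_side)
        resized = _resize(cropped, config.out_side)
        gray = to_gray(resized)
        out[t] = binarize(gray, config.binarize_threshold)
    return BinaryDiffStack(out, source_id=video.source_id, fps=video.fps, config=config)


def diff_labels(track: LabelTrack | Sequence[int]) -> LabelTrack:
    """Align a per-raw-frame label track to the diff stack (drop frame 0)."""
    track = as_track(track)
    if len(track) < 2:
        raise ValueError("label track too short to align to a diff stack")
    return LabelTrack(track.values[1:], source_id=track.source_id)


VALID_HALF_WINDOWS = (10, 20, 30, 40)


@dataclass
class GroupedImage:
    """(2w+1)-deep binary stack centered at diff-stack time ``t``."""

    stack: np.ndarray  # (2w+1, S, S) uint8 in {0,1}
    t: int
    w: int

    def __post_init__(self) -> None:
        if self.stack.shape[0] != 2 * self.w + 1:
            raise ValueError(
                f"grouped stack depth {self.stack.shape[0]} != 2w+1 = {2 * self.w + 1}"
            )


def make_grouped(
    stack: BinaryDiffStack,
    labels: LabelTrack | Sequence[int] | None,
    w: int,
    strict_w: bool = True,
) -> list[tuple[GroupedImage, int | None]]:
    """Slice a diff stack into (grouped image, label) pairs at stride 1.

    One grouped image per valid center ``t`` in ``[w, len(stack)-1-w]``; its
    label is the label at ``t`` (``None`` when no track is given).  Slices
    are views into the stack, not copies.
    """
    if strict_w and w not in VALID_HALF_WINDOWS:
        raise ValueError(f"half-window must be one of {VALID_HALF_WINDOWS}, got {w}")
    if w < 1:
        raise ValueError("half-window must be >= 1")
    track = None if labels is None else as_track(labels)
    if track is not None and len(track) != len(stack):
        raise ValueError(f"label track length {len(track)} != stack length {len(stack)}")
    n = len(stack)
    if n < 2 * w + 1:
        warnings.warn(
            f"stack of length {n} shorter than window {2 * w + 1}; no grouped images",
            stacklevel=2,
        )
        return []
    out = []
    for t in range(w, n - w):
        gi = GroupedImage(stack.frames[t - w:t + w + 1], t=t, w=w)
        out.append((gi, None if track is None else int(track.values[t])))
    return out


# ---------------------------------------------------------------------------
# Persistence: compressed array file + metadata.
# ---------------------------------------------------------------------------

def save_stack(stack: BinaryDiffStack, path: str | Path) -> None:
    import json

    meta = {
        "source_id": stack.source_id,
        "fps": stack.fps,
        "config": vars(stack.config).copy(),
    }
    np.savez_compressed(Path(path), frames=stack.frames, meta=json.dumps(meta))


def load_stack(path: str | Path) -> BinaryDiffStack:
    import json

    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        return BinaryDiffStack(
            data["frames"],
            source_id=meta["source_id"],
            fps=meta["fps"],
            config=PreprocessConfig(**meta["config"]),
        )
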