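"""Per-frame behavior label tracks, bout segmentation, and annotation validation.

Label encoding: 0 = not grooming, 1 = facial grooming, 2 = body grooming.
A *bout* is a maximal run of consecutive frames sharing one grooming class;
intervals are half-open ``[start, end)`` with 0-based frame indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

NOT_GROOMING = 0
FACIAL = 1
BODY = 2
VALID_LABELS = (NOT_GROOMING, FACIAL, BODY)
GROOMING_CLASSES = (FACIAL, BODY)

#: annotation contract: a grooming bout lasts at least this many frames
MIN_BOUT_FRAMES = 5
#: annotation contract: consecutive bouts are separated by at least this many frames
MIN_GAP_FRAMES = 6


class LabelError(ValueError):
    """Raised when a label track violates the 0/1/2 encoding contract."""


@dataclass
class LabelTrack:
    """A per-frame integer label sequence for one video.

    Parameters
    ----------
    values
        Sequence of integers in {0, 1, 2}, one per frame.
    source_id
        Identifier of the originating video (free-form).
    """

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 1 or arr.size == 0:
            raise LabelError("label track must be a non-empty 1-D sequence")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise LabelError("label track must contain integers")
            arr = arr.astype(np.int64)
        bad = ~np.isin(arr, VALID_LABELS)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise LabelError(f"invalid label {arr[i]} at frame {i}; labels must be 0, 1 or 2")
        object.__setattr__(self, "values", arr.astype(np.int64))

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTrack):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __getitem__(self, item):
        return self.values[item]


def as_track(track: "LabelTrack | Sequence[int] | np.ndarray", source_id: str = "") -> LabelTrack:
    """Coerce an array-like of labels into a :class:`LabelTrack`."""
    if isinstance(track, LabelTrack):
        return track
    return LabelTrack(np.asarray(track), source_id=source_id)


@dataclass(frozen=True)
class Bout:
    """A maximal constant-class grooming run, ``[start, end)``."""

    cls: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.cls not in GROOMING_CLASSES:
            raise LabelError(f"bout class must be 1 or 2, got {self.cls}")
        if self.end <= self.start:
            raise LabelError("bout must satisfy end > start")

    @property
    def duration(self) -> int:
        return self.end - self.start


def label_runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a label array into ``(label, start, end)`` triples.

    Runs are maximal, consecutive, non-overlapping and cover the whole track.
    """
    arr = np.asarray(values)
    if arr.size == 0:
        return []
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    return [(int(arr[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def extract_bouts(track: LabelTrack | Sequence[int]) -> list[Bout]:
    """Segment a track into grooming bouts (maximal constant-class runs of 1 or 2)."""
    track = as_track(track)
    return [
        Bout(label, start, end)
        for label, start, end in label_runs(track.values)
        if label in GROOMING_CLASSES
    ]


@dataclass(frozen=True)
class Violation:
    """One departure from the bout-duration / bout-interval annotation contract."""

    kind: str  # "short_bout" | "short_gap"
    start: int
    end: int
    length: int

    def __str__(self) -> str:
        what = "bout" if self.kind == "short_bout" else "between-bout gap"
        return f"{what} [{self.start}, {self.end}) lasts {self.length} frames"


def validate_annotation(
    track: LabelTrack | Sequence[int],
    min_bout: int = MIN_BOUT_FRAMES,
    min_gap: int = MIN_GAP_FRAMES,
) -> list[Violation]:
    """Check a ground-truth track against the annotation contract.

    Every grooming bout must last at least ``min_bout`` frames and every
    not-grooming gap *between* two bouts must last at least ``min_gap``
    frames.  Returns the (possibly empty) list of violations; an empty
    report means the track conforms.
    """
    track = as_track(track)
    runs = label_runs(track.values)
    report: list[Violation] = []
    for i, (label, start, end) in enumerate(runs):
        length = end - start
        if label in GROOMING_CLASSES and length < min_bout:
            report.append(Violation("short_bout", start, end, length))
        if (
            label == NOT_GROOMING
            and 0 < i < len(runs) - 1  # leading/trailing zeros are not gaps
            and length < min_gap
        ):
            report.append(Violation("short_gap", start, end, length))
    return report


def to_onehot(track: LabelTrack | Sequence[int]) -> np.ndarray:
    """Convert labels to (n, 3) one-hot float vectors; row ``argmax`` inverts it."""
    track = as_track(track)
    out = np.zeros((len(track), 3), dtype=np.float64)
    out[np.arange(len(track)), track.values] = 1.0
    return out


# ---------------------------------------------------------------------------
# CSV I/O — header `frame,label`, 0-based contiguous frame index.
# ---------------------------------------------------------------------------

def read_label_csv(path: str | Path, source_id: str | None = None) -> LabelTrack:
    """Read a strict ``frame,label`` CSV; errors carry 1-based line numbers."""
    path = Path(path)
    values: list[int] = []
    with path.open() as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        if cols[:2] != ["frame", "label"]:
            raise LabelError(f"{path}:1: expected header 'frame,label', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise LabelError(f"{path}:{lineno}: expected 'frame,label' row, got {line!r}")
            try:
                frame, label = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise LabelError(f"{path}:{lineno}: non-integer field in {line!r}") from exc
            if frame != len(values):
                raise LabelError(
                    f"{path}:{lineno}: frame index {frame} out of order (expected {len(values)})"
                )
            if label not in VALID_LABELS:
                raise LabelError(f"{path}:{lineno}: invalid label {label}")
            values.append(label)
    if not values:
        raise LabelError(f"{path}: no label rows")
    return LabelTrack(np.array(values), source_id=source_id or path.stem)


def write_label_csv(track: LabelTrack | Sequence[int], path: str | Path,
                    label_column: str = "label") -> None:
    track = as_track(track)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"frame,{label_column}\n")
        for i, v in enumerate(track.values):
            fh.write(f"{i},{int(v)}\n")
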