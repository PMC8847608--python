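"""Rule-based posterior filters for predicted label tracks.

Three implausible patterns are serially reversed, in this order:

1. *sporadic* — a grooming run of at most ``sporadic_max`` frames flanked by
   not-grooming on both sides (the video boundary counts as not-grooming) is
   erased;
2. *interruption* — a not-grooming gap of at most ``interruption_max`` frames
   sandwiched between two grooming runs is filled;
3. *transition* — a grooming run of at most ``transition_max`` frames
   adjacent to a run of the other grooming class is relabeled to that class.

Each filter repeatedly rewrites the leftmost remaining instance until its
pattern is extinct, so the stage post-condition holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import GROOMING_CLASSES, NOT_GROOMING, LabelTrack, as_track, label_runs


@dataclass(frozen=True)
class FilterParams:
    """Thresholds (in frames) for the three posterior filters."""

    sporadic_max: int = 4
    interruption_max: int = 6
    transition_max: int = 4

    def __post_init__(self) -> None:
        for name in ("sporadic_max", "interruption_max", "transition_max"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")


def _rewrite_until_stable(values: np.ndarray, find_rewrite) -> np.ndarray:
    """Apply ``find_rewrite(runs) -> (start, end, new_label) | None`` to a fixpoint."""
    out = values.copy()
    while True:
        hit = find_rewrite(label_runs(out))
        if hit is None:
            return out
        start, end, new_label = hit
        out[start:end] = new_label


def filter_sporadic(track: LabelTrack, max_len: int = 4) -> LabelTrack:
    """Erase grooming runs of length <= ``max_len`` flanked by 0 on both sides.

    The video boundary counts as a 0-neighbor.
    """
    track = as_track(track)

    def find(runs):
        for i, (label, start, end) in enumerate(runs):
            if label not in GROOMING_CLASSES or end - start > max_len:
                continue
            left_zero = i == 0 or runs[i - 1][0] == NOT_GROOMING
            right_zero = i == len(runs) - 1 or runs[i + 1][0] == NOT_GROOMING
            if left_zero and right_zero:
                return start, end, NOT_GROOMING
        return None

    return LabelTrack(_rewrite_until_stable(track.values, find), source_id=track.source_id)


def filter_interruption(track: LabelTrack, max_gap: int = 6) -> LabelTrack:
    """Fill 0-gaps of length <= ``max_gap`` sandwiched between grooming runs.

    When the flanking runs disagree on class the longer flank wins; a tie goes
    to the preceding run's class.
    """
    track = as_track(track)

    def find(runs):
        for i in range(1, len(runs) - 1):
            label, start, end = runs[i]
            if label != NOT_GROOMING or end - start > max_gap:
                continue
            lc, ls, le = runs[i - 1]
            rc, rs, re = runs[i + 1]
            if lc not in GROOMING_CLASSES or rc not in GROOMING_CLASSES:
                continue
            if lc == rc:
                fill = lc
            else:
                fill = lc if (le - ls) >= (re - rs) else rc
            return start, end, fill
        return None

    return LabelTrack(_rewrite_until_stable(track.values, find), source_id=track.source_id)


def filter_transition(track: LabelTrack, max_len: int = 4) -> LabelTrack:
    """Relabel short grooming runs adjacent to the other grooming class.

    A run of class c in {1, 2} of length <= ``max_len`` whose immediate
    neighbor (either side) is the other grooming class is absorbed into that
    class.  With two grooming classes the other class is unique, so the
    sandwich case needs no arbitration.
    """
    track = as_track(track)

    def find(runs):
        for i, (label, start, end) in enumerate(runs):
            if label not in GROOMING_CLASSES or end - start > max_len:
                continue
            other = FACIAL_BODY_SWAP[label]
            left_other = i > 0 and runs[i - 1][0] == other
            right_other = i < len(runs) - 1 and runs[i + 1][0] == other
            if left_other or right_other:
                return start, end, other
        return None

    return LabelTrack(_rewrite_until_stable(track.values, find), source_id=track.source_id)


FACIAL_BODY_SWAP = {1: 2, 2: 1}


def apply_filters(track: LabelTrack, params: FilterParams | None = None) -> LabelTrack:
    """One serial pass: sporadic -> interruption -> transition."""
    params = params or FilterParams()
    track = as_track(track)
    track = filter_sporadic(track, params.sporadic_max)
    track = filter_interruption(track, params.interruption_max)
    track = filter_transition(track, params.transition_max)
    return track
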