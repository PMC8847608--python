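"""Synthetic top-view behavior videos with ground-truth labels.

A bright ellipse "mouse" moves on a dark square arena.  Four scripted
behaviors are rendered: ``still`` (no motion), ``locomote`` (rigid
translation with heading jitter), ``facial_groom`` (small, fast appendage
oscillation at the anterior pole) and ``body_groom`` (larger, slower bulge
oscillation at the flank).  Ground-truth tracks satisfy the annotation
contract by construction (bouts >= 5 frames, gaps >= 6 frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .labels import (GROOMING_CLASSES, MIN_BOUT_FRAMES, MIN_GAP_FRAMES,
                     LabelTrack, as_track, extract_bouts)

BEHAVIORS = ("still", "locomote", "facial_groom", "body_groom")
BEHAVIOR_LABELS = {"still": 0, "locomote": 0, "facial_groom": 1, "body_groom": 2}


@dataclass(frozen=True)
class Segment:
    behavior: str
    duration: int

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.duration < 1:
            raise ValueError("segment duration must be >= 1")

    @property
    def label(self) -> int:
        return BEHAVIOR_LABELS[self.behavior]


@dataclass
class BehaviorScript:
    """Ordered behavior segments; grooming segments obey the bout contract."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        self.segments = [
            seg if isinstance(seg, Segment) else Segment(*seg) for seg in self.segments
        ]
        if not self.segments:
            raise ValueError("script must contain at least one segment")
        gap_since_groom: int | None = None
        for seg in self.segments:
            if seg.label in GROOMING_CLASSES:
                if seg.duration < MIN_BOUT_FRAMES:
                    raise ValueError(
                        f"grooming segment of {seg.duration} frames "
                        f"(minimum {MIN_BOUT_FRAMES})"
                    )
                if gap_since_groom is not None and gap_since_groom < MIN_GAP_FRAMES:
                    raise ValueError(
                        f"grooming segments separated by {gap_since_groom} "
                        f"non-grooming frames (minimum {MIN_GAP_FRAMES})"
                    )
                gap_since_groom = 0
            elif gap_since_groom is not None:
                gap_since_groom += seg.duration

    @property
    def total_frames(self) -> int:
        return sum(seg.duration for seg in self.segments)

    def to_labels(self, source_id: str = "") -> LabelTrack:
        values = np.concatenate([
            np.full(seg.duration, seg.label, dtype=np.int64) for seg in self.segments
        ])
        return LabelTrack(values, source_id=source_id)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and motion parameters of the rendered scene."""

    arena_side: int = 256
    body_axes: tuple[float, float] = (20.0, 12.0)  # ellipse semi-axes (along, across)
    locomotion_speed: float = 1.5  # px/frame
    facial_osc: tuple[float, int] = (2.0, 4)  # (amplitude px, period frames)
    body_osc: tuple[float, int] = (8.0, 8)
    pixel_noise_rate: float = 0.0
    seed: int = 0
    fps: float = 60.0

    def __post_init__(self) -> None:
        if self.arena_side < 32:
            raise ValueError("arena_side too small")
        if self.facial_osc[0] <= 0 or self.body_osc[0] <= 0:
            raise ValueError("oscillation amplitudes must be positive")
        if self.facial_osc[0] >= self.body_osc[0]:
            raise ValueError("facial amplitude must be smaller than body amplitude")
        if not 0.0 <= self.pixel_noise_rate <= 0.05:
            raise ValueError("pixel_noise_rate must be in [0, 0.05]")


def _disk(canvas: np.ndarray, rr: np.ndarray, cc: np.ndarray,
          center: tuple[float, float], radius: float) -> None:
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    canvas[mask] = 255


def render_video(script: BehaviorScript, scene: SceneConfig,
                 source_id: str = "synthetic") -> tuple[np.ndarray, LabelTrack]:
    """Render a script into (T, S, S) uint8 frames plus the truth track."""
    rng = np.random.default_rng(scene.seed)
    side = scene.arena_side
    a, b = scene.body_axes
    margin = a + scene.body_osc[0] + 8
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")

    pos = np.array([side / 2, side / 2], dtype=np.float64)
    pos += rng.uniform(-side / 8, side / 8, size=2)
    heading = float(rng.uniform(0, 2 * np.pi))
    clipped = False

    frames = np.zeros((script.total_frames, side, side), dtype=np.uint8)
    t = 0
    for seg in script.segments:
        for phase in range(seg.duration):
            if seg.behavior == "locomote":
                heading += float(rng.normal(0.0, 0.06))
                pos += scene.locomotion_speed * np.array([np.sin(heading), np.cos(heading)])
                lo, hi = margin, side - 1 - margin
                if (pos < lo).any() or (pos > hi).any():
                    if not clipped:
                        warnings.warn("mouse reached the arena wall; clipping", stacklevel=2)
                        clipped = True
                    pos = np.clip(pos, lo, hi)
                    heading += np.pi / 2  # bounce away from the wall

            along = np.array([np.sin(heading), np.cos(heading)])
            across = np.array([np.cos(heading), -np.sin(heading)])
            d = np.stack([rr - pos[0], cc - pos[1]])
            u = d[0] * along[0] + d[1] * along[1]
            v = d[0] * across[0] + d[1] * across[1]
            canvas = np.where((u / a) ** 2 + (v / b) ** 2 <= 1.0, 255, 0).astype(np.uint8)

            if seg.behavior == "facial_groom":
                amp, period = scene.facial_osc
                off = amp * np.sin(2 * np.pi * phase / period)
                center = pos + a * along + off * across
                _disk(canvas, rr, cc, (center[0], center[1]), radius=3.0)
            elif seg.behavior == "body_groom":
                amp, period = scene.body_osc
                off = amp * (0.5 + 0.5 * np.sin(2 * np.pi * phase / period))
                center = pos + (b - 2.0 + off) * across
                _disk(canvas, rr, cc, (center[0], center[1]), radius=6.0)

            if scene.pixel_noise_rate > 0:
                noisy = rng.random((side, side)) < scene.pixel_noise_rate
                canvas[noisy] = 255 - canvas[noisy]
            frames[t] = canvas
            t += 1
    return frames, script.to_labels(source_id=source_id)


def random_script(
    rng: np.random.Generator,
    n_bouts: int,
    class_mix: tuple[float, float] = (0.4, 0.6),
    bout_frames: tuple[int, int] = (20, 60),
    rest_frames: tuple[int, int] = (12, 40),
    p_locomote: float = 0.5,
) -> BehaviorScript:
    """Random alternating rest/grooming script with ``n_bouts`` grooming segments.

    ``class_mix`` gives (facial, body) probabilities.  Rest segments are at
    least ``MIN_GAP_FRAMES`` long by construction, so scripts always satisfy
    the annotation contract.
    """
    if n_bouts < 0:
        raise ValueError("n_bouts must be >= 0")
    if rest_frames[0] < MIN_GAP_FRAMES:
        raise ValueError(f"rest segments must be >= {MIN_GAP_FRAMES} frames")
    if bout_frames[0] < MIN_BOUT_FRAMES:
        raise ValueError(f"grooming segments must be >= {MIN_BOUT_FRAMES} frames")
    mix = np.asarray(class_mix, dtype=float)
    mix = mix / mix.sum()
    segments: list[Segment] = []

    def rest() -> None:
        behavior = "locomote" if rng.random() < p_locomote else "still"
        segments.append(Segment(behavior, int(rng.integers(rest_frames[0], rest_frames[1] + 1))))

    rest()
    for _ in range(n_bouts):
        groom = "facial_groom" if rng.random() < mix[0] else "body_groom"
        segments.append(Segment(groom, int(rng.integers(bout_frames[0], bout_frames[1] + 1))))
        rest()
    return BehaviorScript(segments)


def generate_video(
    seed: int,
    n_bouts: int = 4,
    scene: SceneConfig | None = None,
    **script_kwargs,
) -> tuple[np.ndarray, LabelTrack, BehaviorScript]:
    """Convenience wrapper: random script + rendering, fully seeded."""
    rng = np.random.default_rng(seed)
    script = random_script(rng, n_bouts, **script_kwargs)
    scene = scene or SceneConfig(seed=seed)
    if scene.seed != seed:
        scene = SceneConfig(**{**vars(scene), "seed": seed})
    frames, truth = render_video(script, scene, source_id=f"synthetic-{seed}")
    return frames, truth, script


# ---------------------------------------------------------------------------
# Track corruption (inverse of the three posterior filters).
# ---------------------------------------------------------------------------

#: corrupted intervals are kept further apart than the interruption filter span
MIN_SEPARATION = 7


class CorruptionError(ValueError):
    pass


def corrupt_track(
    truth: LabelTrack | Sequence[int],
    rng: np.random.Generator,
    rates: tuple[float, float, float] = (0.004, 0.004, 0.004),
    max_tries: int = 200,
) -> LabelTrack:
    """Inject filter-reversible perturbations into a ground-truth track.

    Three kinds are injected at the given per-eligible-frame rates:
    (a) *sporadic* — grooming runs of <= 4 frames deep inside not-grooming
    stretches, (b) *gap* — 0-runs of <= 6 frames strictly inside bouts with
    >= 5 bout frames left on both sides, (c) *transition* — <= 4 frame class
    flips at bout edges.  Injections are mutually separated by more than 6
    frames, so ``apply_filters`` restores the exact truth.
    """
    truth = as_track(truth)
    values = truth.values.copy()
    n = len(truth)
    bouts = extract_bouts(truth)
    n_groom = int(np.count_nonzero(truth.values))
    n_zero = n - n_groom
    counts = (
        int(rng.binomial(n_zero, rates[0])) if n_zero else 0,
        int(rng.binomial(n_groom, rates[1])) if n_groom else 0,
        int(rng.binomial(n_groom, rates[2])) if n_groom else 0,
    )
    placed: list[tuple[int, int]] = []

    def far_enough(s: int, e: int) -> bool:
        return all(s >= pe + MIN_SEPARATION or ps >= e + MIN_SEPARATION
                   for ps, pe in placed)

    def place(kind: str) -> None:
        # gap/transition sites are scarce (few bouts, two edges each); when a
        # draw cannot be placed without violating separation the injection is
        # dropped rather than failing the whole track
        for _ in range(max_tries):
            if kind == "sporadic":
                length = int(rng.integers(1, 5))
                s = int(rng.integers(0, n - length + 1))
                e = s + length
                lo, hi = max(0, s - MIN_SEPARATION), min(n, e + MIN_SEPARATION)
                if np.any(truth.values[lo:hi] != 0):
                    continue
                if not far_enough(s, e):
                    continue
                values[s:e] = int(rng.choice(GROOMING_CLASSES))
                placed.append((s, e))
                return
            elif kind == "gap":
                length = int(rng.integers(1, MIN_GAP_FRAMES + 1))
                eligible = [bt for bt in bouts if bt.duration >= length + 2 * MIN_BOUT_FRAMES]
                if not eligible:
                    break
                bt = eligible[int(rng.integers(0, len(eligible)))]
                s = int(rng.integers(bt.start + MIN_BOUT_FRAMES,
                                     bt.end - MIN_BOUT_FRAMES - length + 1))
                e = s + length
                if not far_enough(s, e):
                    continue
                values[s:e] = 0
                placed.append((s, e))
                return
            else:  # transition flip at a bout edge
                length = int(rng.integers(1, 5))
                eligible = [bt for bt in bouts if bt.duration >= length + MIN_BOUT_FRAMES]
                if not eligible:
                    break
                bt = eligible[int(rng.integers(0, len(eligible)))]
                if rng.random() < 0.5:
                    s, e = bt.start, bt.start + length
                else:
                    s, e = bt.end - length, bt.end
                if not far_enough(s, e):
                    continue
                values[s:e] = 1 if bt.cls == 2 else 2
                placed.append((s, e))
                return
        else:
            if kind == "sporadic":
                raise CorruptionError(
                    f"could not place a {kind} corruption with separation "
                    f">= {MIN_SEPARATION} after {max_tries} tries; lower the rates"
                )

    # edge flips have the fewest candidate sites, so place them first
    order = (("transition", counts[2]), ("gap", counts[1]), ("sporadic", counts[0]))
    for kind, count in order:
        for _ in range(count):
            place(kind)
    return LabelTrack(values, source_id=truth.source_id)
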