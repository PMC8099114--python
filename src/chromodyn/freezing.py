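"""Automatic freezing scorer for fear-conditioning behavior videos.

Freezing (immobility) is scored from the movement rate: consecutive frames
are differenced, pixels changing by more than a grey-level threshold count
as "significant motion pixels", and a frame pair is still when that count
does not exceed a motion threshold. Maximal runs of still pairs lasting at
least a minimum bout duration are freezing bouts; per-period freezing is
the fraction of the period covered by bouts. The baseline period defaults
to the 30-60 s silence window of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BehaviorVideo", "FreezingReport", "motion_pixels", "score_freezing"]


@dataclass(frozen=True)
class BehaviorVideo:
    """An ordered frame sequence with its experimental period schedule.

    ``frames`` is ``(t, y, x)`` grayscale or ``(t, y, x, c)`` color (colors
    are averaged to luminance when scored); ``event_schedule`` lists
    ``(label, start_s, end_s)`` periods, e.g. baseline and CS presentations.
    """

    frames: np.ndarray
    fps: float
    event_schedule: tuple[tuple[str, float, float], ...] = (("baseline", 30.0, 60.0),)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        frames = np.asarray(self.frames)
        if frames.ndim not in (3, 4):
            raise ValueError("frames must be (t, y, x) or (t, y, x, c)")
        dur = frames.shape[0] / self.fps
        for label, a, b in self.event_schedule:
            if not (0 <= a < b <= dur + 1e-9):
                raise ValueError(
                    f"period {label!r} [{a}, {b}] s lies outside the video (duration {dur:.2f} s)"
                )
        object.__setattr__(self, "frames", frames)

    @property
    def duration_s(self) -> float:
        return self.frames.shape[0] / self.fps

    def grayscale(self) -> np.ndarray:
        f = self.frames.astype(float)
        return f.mean(axis=-1) if f.ndim == 4 else f


@dataclass(frozen=True)
class FreezingReport:
    fractions: dict  # period label -> freezing fraction in [0, 1]
    motion_counts: np.ndarray  # per frame pair
    bouts: tuple[tuple[float, float], ...]  # (start_s, end_s), non-overlapping

    def __post_init__(self) -> None:
        for label, f in self.fractions.items():
            if not (0.0 <= f <= 1.0 + 1e-12):
                raise ValueError(f"fraction for {label!r} outside [0, 1]: {f}")


def motion_pixels(frame_a: np.ndarray, frame_b: np.ndarray, pixel_delta_threshold: float) -> int:
    """Count pixels whose absolute change exceeds ``pixel_delta_threshold``."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(np.abs(a - b) > pixel_delta_threshold))


def score_freezing(
    video: BehaviorVideo,
    pixel_delta_threshold: float = 25.0,
    motion_count_threshold: int = 50,
    min_bout_s: float = 1.0,
) -> FreezingReport:
    """Score per-period freezing fractions of a behavior video.

    Frame pair ``i`` (frames ``i`` and ``i+1``) covers the time interval
    ``[i/fps, (i+1)/fps)`` and is still when its significant-motion-pixel
    count is at most ``motion_count_threshold``. Maximal runs of still pairs
    of duration >= ``min_bout_s`` become freezing bouts, and bout time is
    attributed to periods by interval intersection (bouts may straddle
    period boundaries). Raising ``motion_count_threshold`` can only enlarge
    the still set, so freezing fractions are monotone in it.
    """
    frames = video.grayscale()
    if frames.shape[0] < 2:
        raise ValueError("video needs at least two frames")
    diffs = np.abs(np.diff(frames, axis=0))
    counts = (diffs > pixel_delta_threshold).sum(axis=(1, 2))
    still = counts <= motion_count_threshold

    bouts: list[tuple[float, float]] = []
    i = 0
    n = still.size
    while i < n:
        if still[i]:
            j = i
            while j + 1 < n and still[j + 1]:
                j += 1
            # a run reaching the final pair covers the last frame's display too
            start = i / video.fps
            end = (j + 1) / video.fps if j < n - 1 else frames.shape[0] / video.fps
            if end - start >= min_bout_s - 1e-9:
                bouts.append((start, end))
            i = j + 1
        else:
            i += 1

    fractions: dict[str, float] = {}
    for label, a, b in video.event_schedule:
        if b - a <= 0:
            raise ValueError(f"period {label!r} has zero duration")
        covered = sum(max(0.0, min(b, e) - max(a, s)) for s, e in bouts)
        fractions[label] = min(covered / (b - a), 1.0)
    return FreezingReport(
        fractions=fractions, motion_counts=counts, bouts=tuple(bouts)
    )
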