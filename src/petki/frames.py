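"""Frame schedules and time-activity curves for dynamic PET.

A dynamic PET acquisition is a sequence of contiguous, non-overlapping
time frames; the scanner reports one decay-corrected activity
concentration per frame and region.  Frame times are kept in seconds
post-injection (as written in list-mode headers); kinetic analysis
works in minutes, so mid-times are exposed in both units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "FramingSchedule",
    "TimeActivityCurve",
    "long_protocol_schedule",
    "short_early_schedule",
    "short_late_schedule",
]


@dataclass(frozen=True)
class FramingSchedule:
    """Ordered list of (start_s, end_s) acquisition frames.

    Frames must be sorted, non-overlapping, and each must have positive
    duration.  The nominal time stamp of a frame is its mid-time.
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        frames = tuple((float(a), float(b)) for a, b in self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise ValueError("schedule must contain at least one frame")
        prev_end = -np.inf
        for k, (a, b) in enumerate(frames):
            if not (np.isfinite(a) and np.isfinite(b)):
                raise ValueError(f"frame {k}: non-finite bounds ({a}, {b})")
            if a >= b:
                raise ValueError(f"frame {k}: start {a} s >= end {b} s")
            if a < prev_end - 1e-9:
                raise ValueError(f"frame {k}: overlaps previous frame")
            prev_end = b

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_s(self) -> np.ndarray:
        return np.array([a for a, _ in self.frames])

    @property
    def end_s(self) -> np.ndarray:
        return np.array([b for _, b in self.frames])

    @property
    def mid_times_s(self) -> np.ndarray:
        return (self.start_s + self.end_s) / 2.0

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return (self.end_s - self.start_s) / 60.0

    @property
    def end_time_min(self) -> float:
        """End of the acquisition (symbol T of the Patlak line), minutes."""
        return self.frames[-1][1] / 60.0

    def select(self, indices: Sequence[int]) -> "FramingSchedule":
        return FramingSchedule(tuple(self.frames[i] for i in indices))

    @staticmethod
    def from_durations(durations_s: Iterable[float], t0_s: float = 0.0) -> "FramingSchedule":
        frames = []
        t = float(t0_s)
        for d in durations_s:
            frames.append((t, t + float(d)))
            t += float(d)
        return FramingSchedule(tuple(frames))


def long_protocol_schedule() -> FramingSchedule:
    """Standard 60-min thorax dynamic framing: 24 x 5 s, 12 x 15 s, 11 x 5 min."""
    return FramingSchedule.from_durations([5.0] * 24 + [15.0] * 12 + [300.0] * 11)


def short_early_schedule() -> FramingSchedule:
    """Early short acquisition (0-10 min): 24 x 5 s, 12 x 15 s, 1 x 5 min."""
    return FramingSchedule.from_durations([5.0] * 24 + [15.0] * 12 + [300.0])


def short_late_schedule() -> FramingSchedule:
    """Late short acquisition (40-60 min): 4 x 5 min starting at 40 min."""
    return FramingSchedule.from_durations([300.0] * 4, t0_s=2400.0)


Role = Literal["plasma", "tissue"]


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame activity concentration (kBq/ml) for one region.

    ``decay_corrected`` must be True for any kinetic analysis; raw
    reconstruction output may contain slightly negative values and is
    accepted only when ``raw=True``.
    """

    schedule: FramingSchedule
    values: np.ndarray
    role: Role = "tissue"
    decay_corrected: bool = True
    raw: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.schedule):
            raise ValueError(
                f"values length {values.shape} does not match "
                f"{len(self.schedule)}-frame schedule"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC contains non-finite values")
        if not self.raw and np.any(values < 0):
            raise ValueError(
                "negative activity in a non-raw TAC; pass raw=True for "
                "uncorrected reconstruction output"
            )

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.schedule.mid_times_min

    def clamped_nonnegative(self) -> "TimeActivityCurve":
        """Floor negative reconstruction-noise values at zero."""
        if np.all(self.values >= 0):
            return self
        import warnings

        warnings.warn(
            f"clamping {int(np.sum(self.values < 0))} negative frame value(s) to 0",
            stacklevel=2,
        )
        return replace(self, values=np.maximum(self.values, 0.0), raw=False)

    def select_frames(self, indices: Sequence[int]) -> "TimeActivityCurve":
        return replace(
            self,
            schedule=self.schedule.select(indices),
            values=self.values[list(indices)],
        )

    def interp(self, t_min: float | np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation at ``t_min`` (minutes).

        Before the first frame mid-time the curve rises linearly from 0
        at t = 0 (activity is zero pre-injection); after the last
        mid-time the last value is held.
        """
        t = np.asarray(t_min, dtype=float)
        mids = self.mid_times_min
        xp = np.concatenate(([0.0], mids)) if mids[0] > 0 else mids
        fp = np.concatenate(([0.0], self.values)) if mids[0] > 0 else self.values
        return np.interp(t, xp, fp)
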