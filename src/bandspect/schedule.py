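"""Acquisition frame schedules for dynamic PET scans."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations (seconds) of the dynamic acquisition frames.

    Frames must be contiguous and non-overlapping with strictly positive
    durations; every time-activity curve in the package is sampled as the
    within-frame average of an underlying continuous model curve.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("start_s and duration_s must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        ends = start + dur
        if not np.allclose(ends[:-1], start[1:]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def total_duration_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + self.duration_s / 2.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"start_s": self.start_s, "duration_s": self.duration_s}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrameSchedule":
        df = pd.read_csv(path)
        return cls(df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float))


def default_frame_schedule() -> FrameSchedule:
    """Default 24-frame, 90-minute schedule of increasing frame length.

    Durations: 4x30 s, 4x60 s, 4x120 s, 6x300 s, 6x460 s (5400 s total),
    first frame starting at 0.
    """
    durations = np.array([30.0] * 4 + [60.0] * 4 + [120.0] * 4 + [300.0] * 6 + [460.0] * 6)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)
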