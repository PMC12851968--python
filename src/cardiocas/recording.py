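"""Beat-interval recording container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RRiRecording", "MS_PER_MIN"]

#: milliseconds per minute — the single time-unit conversion in the package
MS_PER_MIN = 60_000.0


@dataclass
class RRiRecording:
    """A beat-to-beat R-R interval series.

    Attributes
    ----------
    beat_times : ndarray
        Monotonically increasing beat times in minutes.
    intervals : ndarray
        R-R intervals in milliseconds, aligned with ``beat_times``.
    artifact_mask : ndarray of bool
        Per-beat exclusion flag (True = excluded from analysis).
    subject_id : str
        Opaque subject label.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    artifact_mask: np.ndarray = None
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, float)
        self.intervals = np.asarray(self.intervals, float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.intervals.shape, bool)
        self.artifact_mask = np.asarray(self.artifact_mask, bool)
        if self.beat_times.shape != self.intervals.shape:
            raise ValueError("beat_times and intervals must have equal length")
        if self.artifact_mask.shape != self.intervals.shape:
            raise ValueError("artifact_mask must match intervals in length")
        if self.intervals.size and np.any(self.intervals <= 0):
            bad = int(np.flatnonzero(self.intervals <= 0)[0])
            raise ValueError(f"nonpositive interval at beat {bad}")
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            bad = int(np.flatnonzero(np.diff(self.beat_times) <= 0)[0]) + 1
            raise ValueError(f"beat_times not strictly increasing at beat {bad}")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def n_beats(self) -> int:
        return self.intervals.size

    @property
    def n_kept(self) -> int:
        return int((~self.artifact_mask).sum())

    @property
    def kept_times(self) -> np.ndarray:
        return self.beat_times[~self.artifact_mask]

    @property
    def kept_intervals(self) -> np.ndarray:
        return self.intervals[~self.artifact_mask]

    @property
    def duration(self) -> float:
        """Span in minutes from the first to the last beat."""
        return float(self.beat_times[-1] - self.beat_times[0]) if len(self) else 0.0

    def copy(self) -> "RRiRecording":
        return RRiRecording(
            self.beat_times.copy(),
            self.intervals.copy(),
            self.artifact_mask.copy(),
            self.subject_id,
        )

    def with_intervals(self, intervals: np.ndarray) -> "RRiRecording":
        return RRiRecording(
            self.beat_times.copy(),
            np.asarray(intervals, float),
            self.artifact_mask.copy(),
            self.subject_id,
        )

    @classmethod
    def from_intervals(
        cls, intervals: np.ndarray, subject_id: str = "subject"
    ) -> "RRiRecording":
        """Build a recording from intervals only, placing the first beat at
        t = 0 and each subsequent beat one interval later."""
        intervals = np.asarray(intervals, float)
        beat_times = np.concatenate([[0.0], np.cumsum(intervals[:-1]) / MS_PER_MIN])
        return cls(beat_times, intervals, subject_id=subject_id)
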