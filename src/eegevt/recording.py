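"""Core containers: multichannel EEG recordings and expert interval markings.

A :class:`Recording` holds a channels x samples signal matrix in microvolts
together with its sampling rate and channel labels; an optional
:class:`Marking` carries labeled time intervals (seizure / artifact / test)
in seconds from recording start.  Intervals are 0-based and half-open,
``[start_s, end_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

VALID_LABELS = ("seizure", "artifact", "test")

#: Electrode names used for synthetic montages, international 10-20 system
#: extended to 25 positions (as in clinical long-term monitoring montages).
CHANNELS_1020_25 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2", "Fpz", "Oz", "A1", "A2", "T1", "T2",
)


@dataclass(frozen=True)
class Interval:
    """A labeled half-open time interval, in seconds."""

    start_s: float
    end_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"interval must have start < end, got [{self.start_s}, {self.end_s})")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, other: "Interval") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s


@dataclass(frozen=True)
class Marking:
    """Expert annotation: a sorted list of labeled intervals."""

    intervals: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.intervals, key=lambda iv: iv.start_s))
        object.__setattr__(self, "intervals", ordered)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def with_label(self, label: str) -> tuple[Interval, ...]:
        return tuple(iv for iv in self.intervals if iv.label == label)

    @property
    def seizures(self) -> tuple[Interval, ...]:
        return self.with_label("seizure")

    @staticmethod
    def from_tuples(rows: Sequence[tuple]) -> "Marking":
        return Marking(tuple(Interval(*row) for row in rows))


@dataclass
class Recording:
    """Multichannel EEG signal with metadata.

    Parameters
    ----------
    signal
        Array of shape (n_channels, n_samples), microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One name per channel (10-20 system for synthetic data).
    marking
        Optional expert marking; ``None`` for unannotated data.
    """

    signal: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = ()
    marking: Marking | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(self.n_channels))
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must match channel count")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.marking is not None:
            for iv in self.marking:
                if iv.start_s < 0 or iv.end_s > self.duration + 1e-9:
                    raise ValueError(
                        f"marking interval [{iv.start_s}, {iv.end_s}) outside recording [0, {self.duration})"
                    )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_signal(self, signal: np.ndarray, **log_updates) -> "Recording":
        """Copy of this recording with a replaced signal matrix (same metadata)."""
        new = replace(self, signal=signal)
        new.log = {**self.log, **log_updates}
        return new
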