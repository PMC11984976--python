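"""Contraction isolation and sliding-window segmentation.

Each trial's 3 s hold is reduced to its central 70 % (35 % either side of
the contraction midpoint) to avoid transitional muscle states, giving
2.1 s of steady contraction per repetition and 6.3 s per condition across
the three repetitions.  Retained segments are then cut into 200 ms windows
advanced in 50 ms steps for feature extraction.

Windowing is applied within each repetition separately so that every
window has unambiguous repetition provenance for leave-one-repetition-out
cross-validation; windows never straddle repetition boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .synthetic_data import ConditionLabel, SessionRecording, TrialEvent

__all__ = [
    "SegmentationParams",
    "ContractionSegment",
    "SignalWindow",
    "extract_contraction",
    "slide_windows",
    "window_stack",
    "iter_segments",
]


@dataclass(frozen=True)
class SegmentationParams:
    keep_fraction: float = 0.70
    window_ms: float = 200.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        if not self.window_ms >= self.step_ms > 0:
            raise ValueError("require window_ms >= step_ms > 0")

    def window_samples(self, rate: float) -> int:
        w = self.window_ms * rate / 1000.0
        if abs(w - round(w)) > 1e-9:
            raise ValueError(
                f"window_ms={self.window_ms} is not an integer number of "
                f"samples at {rate} Hz"
            )
        return int(round(w))

    def step_samples(self, rate: float) -> int:
        s = self.step_ms * rate / 1000.0
        if abs(s - round(s)) > 1e-9:
            raise ValueError(
                f"step_ms={self.step_ms} is not an integer number of samples "
                f"at {rate} Hz"
            )
        return int(round(s))


@dataclass
class ContractionSegment:
    """Central portion of one contraction, channels aligned sample-for-sample."""

    emg: np.ndarray  # (8, M)
    fmg: np.ndarray  # (8, M)
    condition: ConditionLabel
    repetition: int
    participant_id: str
    sample_rate_hz: float


@dataclass
class SignalWindow:
    emg: np.ndarray  # (8, W)
    fmg: np.ndarray  # (8, W)
    condition: ConditionLabel
    repetition: int
    participant_id: str
    window_index: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def extract_contraction(
    recording: SessionRecording,
    event: TrialEvent,
    params: SegmentationParams = SegmentationParams(),
) -> ContractionSegment:
    """Samples spanning ``[mid - keep/2 * dur, mid + keep/2 * dur)``.

    The retained sample count is keep_fraction x duration x rate rounded
    half-up; the segment is centred on the contraction-midpoint sample
    (index ``floor(t_mid * rate)``).
    """
    rate = recording.sample_rate_hz
    duration = event.contraction_offset_s - event.contraction_onset_s
    n_keep = _round_half_up(params.keep_fraction * duration * rate)
    mid_idx = int(math.floor((event.contraction_onset_s + duration / 2.0) * rate))
    start = mid_idx - n_keep // 2
    stop = start + n_keep
    if start < 0 or stop > recording.n_samples:
        raise ValueError(
            f"event [{event.contraction_onset_s}, {event.contraction_offset_s}) s "
            f"lies outside the recording of {recording.n_samples} samples"
        )
    return ContractionSegment(
        emg=recording.emg[:, start:stop],
        fmg=recording.fmg[:, start:stop],
        condition=event.condition,
        repetition=event.repetition,
        participant_id=recording.participant_id,
        sample_rate_hz=rate,
    )


def _window_starts(m: int, w: int, s: int) -> np.ndarray:
    if m < w:
        raise ValueError(
            f"segment of {m} samples is shorter than one {w}-sample window"
        )
    count = (m - w) // s + 1
    return np.arange(count) * s


def slide_windows(
    segment: ContractionSegment, params: SegmentationParams = SegmentationParams()
) -> list[SignalWindow]:
    """Cut a segment into fully contained, ordered sliding windows."""
    w = params.window_samples(segment.sample_rate_hz)
    s = params.step_samples(segment.sample_rate_hz)
    starts = _window_starts(segment.emg.shape[1], w, s)
    return [
        SignalWindow(
            emg=segment.emg[:, a : a + w],
            fmg=segment.fmg[:, a : a + w],
            condition=segment.condition,
            repetition=segment.repetition,
            participant_id=segment.participant_id,
            window_index=i,
        )
        for i, a in enumerate(starts)
    ]


def window_stack(
    segment: ContractionSegment, params: SegmentationParams = SegmentationParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Windows of a segment as two (n_windows, 8, W) strided views.

    Equivalent to :func:`slide_windows` but returned as arrays for
    vectorised feature extraction.
    """
    w = params.window_samples(segment.sample_rate_hz)
    s = params.step_samples(segment.sample_rate_hz)
    starts = _window_starts(segment.emg.shape[1], w, s)

    def stack(x: np.ndarray) -> np.ndarray:
        view = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)
        return view[:, starts, :].transpose(1, 0, 2)

    return stack(segment.emg), stack(segment.fmg)


def iter_segments(
    recording: SessionRecording, params: SegmentationParams = SegmentationParams()
) -> Iterator[ContractionSegment]:
    """Contraction segments for every event of a session, in schedule order."""
    for ev in recording.events:
        yield extract_contraction(recording, ev, params)
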