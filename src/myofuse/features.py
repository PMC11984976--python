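"""Time-domain feature extraction and stacked multimodal fusion.

EMG windows are summarised by the Hudgins time-domain set — mean absolute
value (MAV), waveform length (WL), zero crossings (ZC), slope sign changes
(SSC) and root mean square (RMS) — per channel; FMG windows by MAV alone.
The fused "stacked" vector is the EMG 40-vector concatenated with the FMG
8-vector, giving 48 features.

Feature ordering is channel-major, then feature in the fixed order
(MAV, WL, ZC, SSC, RMS).  ZC and SSC accept an amplitude deadband
(threshold) that suppresses counts driven by the noise floor; the default
thresholds are zero, i.e. the textbook definitions.  A helper derives
per-channel deadbands from rest-phase noise when that behaviour is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import (
    SegmentationParams,
    SignalWindow,
    iter_segments,
    window_stack,
)
from .synthetic_data import ConditionLabel, N_CHANNELS, SessionRecording

__all__ = [
    "EMG_FEATURE_NAMES",
    "MODALITIES",
    "FeatureParams",
    "FeatureVector",
    "mav",
    "rms",
    "waveform_length",
    "zero_crossings",
    "slope_sign_changes",
    "extract_features",
    "emg_feature_matrix",
    "fmg_feature_matrix",
    "modality_columns",
    "feature_columns",
    "feature_table",
    "rest_noise_thresholds",
]

EMG_FEATURE_NAMES: tuple[str, ...] = ("mav", "wl", "zc", "ssc", "rms")
MODALITIES: tuple[str, ...] = ("emg", "fmg", "emg_fmg")

LABEL_COLUMNS = (
    "participant_id",
    "gesture",
    "load_g",
    "position",
    "repetition",
    "window_index",
)


@dataclass
class FeatureParams:
    """Amplitude deadbands for the crossing-count features.

    Scalars apply to every channel; arrays give a per-channel deadband.
    Zero (the default) reproduces the unthresholded textbook definitions.
    """

    zc_threshold: float | np.ndarray = 0.0
    ssc_threshold: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.zc_threshold) < 0) or np.any(
            np.asarray(self.ssc_threshold) < 0
        ):
            raise ValueError("deadband thresholds must be >= 0")

    def channel_thresholds(self, n_channels: int) -> tuple[np.ndarray, np.ndarray]:
        zc = np.broadcast_to(np.asarray(self.zc_threshold, float), (n_channels,))
        ssc = np.broadcast_to(np.asarray(self.ssc_threshold, float), (n_channels,))
        return zc, ssc


@dataclass
class FeatureVector:
    modality: str
    values: np.ndarray
    condition: ConditionLabel
    repetition: int
    participant_id: str
    window_index: int = 0


def _as_window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D single-channel window")
    return x


def mav(x: Sequence[float]) -> float:
    """Mean absolute value."""
    x = _as_window(x)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def rms(x: Sequence[float]) -> float:
    """Root mean square."""
    x = _as_window(x)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x**2)))


def waveform_length(x: Sequence[float]) -> float:
    """Cumulative length of the waveform: sum of absolute first differences."""
    x = _as_window(x)
    if x.size < 2:
        raise ValueError("waveform length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def zero_crossings(x: Sequence[float], threshold: float = 0.0) -> int:
    """Sign changes between consecutive samples exceeding the deadband.

    A crossing is counted where the signs strictly oppose (``x_i * x_{i+1}
    < 0``) and the step ``|x_i - x_{i+1}|`` is at least ``threshold``.
    Exact zeros are sign-neutral and never produce a crossing.
    """
    x = _as_window(x)
    if x.size < 2:
        raise ValueError("zero crossings need at least 2 samples")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    opposed = x[:-1] * x[1:] < 0
    big_enough = np.abs(np.diff(x)) >= threshold
    return int(np.count_nonzero(opposed & big_enough))


def slope_sign_changes(x: Sequence[float], threshold: float = 0.0) -> int:
    """Interior local extrema whose larger adjacent step exceeds the deadband."""
    x = _as_window(x)
    if x.size < 3:
        raise ValueError("slope sign changes need at least 3 samples")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    d_prev = x[1:-1] - x[:-2]
    d_next = x[1:-1] - x[2:]
    extremum = d_prev * d_next > 0
    big_enough = np.maximum(np.abs(d_prev), np.abs(d_next)) >= threshold
    return int(np.count_nonzero(extremum & big_enough))


def emg_feature_matrix(
    windows: np.ndarray, params: FeatureParams = FeatureParams()
) -> np.ndarray:
    """Hudgins-set features for a stack of EMG windows.

    ``windows`` is (n_windows, n_channels, W); the result is
    (n_windows, n_channels * 5), channel-major with features ordered
    (MAV, WL, ZC, SSC, RMS).
    """
    x = np.asarray(windows, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (n_windows, n_channels, W)")
    n, c, w = x.shape
    if w < 3:
        raise ValueError("windows must hold at least 3 samples")
    zc_t, ssc_t = params.channel_thresholds(c)

    mav_ = np.mean(np.abs(x), axis=2)
    d = np.diff(x, axis=2)
    wl_ = np.sum(np.abs(d), axis=2)
    opposed = x[:, :, :-1] * x[:, :, 1:] < 0
    zc_ = np.count_nonzero(opposed & (np.abs(d) >= zc_t[None, :, None]), axis=2)
    d_prev = x[:, :, 1:-1] - x[:, :, :-2]
    d_next = x[:, :, 1:-1] - x[:, :, 2:]
    ssc_ = np.count_nonzero(
        (d_prev * d_next > 0)
        & (np.maximum(np.abs(d_prev), np.abs(d_next)) >= ssc_t[None, :, None]),
        axis=2,
    )
    rms_ = np.sqrt(np.mean(x**2, axis=2))

    out = np.stack([mav_, wl_, zc_.astype(float), ssc_.astype(float), rms_], axis=2)
    return out.reshape(n, c * len(EMG_FEATURE_NAMES))


def fmg_feature_matrix(windows: np.ndarray) -> np.ndarray:
    """Per-channel MAV for a stack of FMG windows: (n_windows, n_channels)."""
    x = np.asarray(windows, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (n_windows, n_channels, W)")
    return np.mean(np.abs(x), axis=2)


def extract_features(
    window: SignalWindow,
    modality: str,
    params: FeatureParams = FeatureParams(),
) -> FeatureVector:
    """Feature vector for one window and modality.

    emg -> 40 values (8 channels x Hudgins set); fmg -> 8 (per-channel
    MAV); emg_fmg -> the 48-value stacked concatenation [emg || fmg].
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    if modality == "emg":
        values = emg_feature_matrix(window.emg[None, :, :], params)[0]
    elif modality == "fmg":
        values = fmg_feature_matrix(window.fmg[None, :, :])[0]
    else:
        values = np.concatenate(
            [
                emg_feature_matrix(window.emg[None, :, :], params)[0],
                fmg_feature_matrix(window.fmg[None, :, :])[0],
            ]
        )
    return FeatureVector(
        modality=modality,
        values=values,
        condition=window.condition,
        repetition=window.repetition,
        participant_id=window.participant_id,
        window_index=window.window_index,
    )


def modality_columns(modality: str) -> list[str]:
    """Feature-table column names carrying the given modality's vector."""
    emg_cols = [
        f"emg{ch}_{f}" for ch in range(N_CHANNELS) for f in EMG_FEATURE_NAMES
    ]
    fmg_cols = [f"fmg{ch}_mav" for ch in range(N_CHANNELS)]
    if modality == "emg":
        return emg_cols
    if modality == "fmg":
        return fmg_cols
    if modality == "emg_fmg":
        return emg_cols + fmg_cols
    raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")


def feature_columns() -> list[str]:
    """All 48 feature columns in stacked order."""
    return modality_columns("emg_fmg")


def feature_table(
    recording: SessionRecording,
    seg_params: SegmentationParams = SegmentationParams(),
    feat_params: FeatureParams = FeatureParams(),
) -> pd.DataFrame:
    """Window-level feature table for a whole session.

    One row per sliding window with provenance labels
    (participant, gesture, load_g, position, repetition, window_index)
    followed by the 48 stacked feature columns.  The first 40 columns of a
    row equal the EMG-only vector of that window; the last 8 the FMG-only
    vector.
    """
    rows_meta = []
    blocks = []
    for seg in iter_segments(recording, seg_params):
        emg_w, fmg_w = window_stack(seg, seg_params)
        feats = np.hstack(
            [emg_feature_matrix(emg_w, feat_params), fmg_feature_matrix(fmg_w)]
        )
        blocks.append(feats)
        g, l, p = seg.condition.as_tuple()
        rows_meta.append(
            pd.DataFrame(
                {
                    "participant_id": seg.participant_id,
                    "gesture": g,
                    "load_g": l,
                    "position": p,
                    "repetition": seg.repetition,
                    "window_index": np.arange(feats.shape[0]),
                }
            )
        )
    meta = pd.concat(rows_meta, ignore_index=True)
    values = pd.DataFrame(np.vstack(blocks), columns=feature_columns())
    return pd.concat([meta, values], axis=1)


def rest_noise_thresholds(
    recording: SessionRecording, factor: float = 0.01
) -> FeatureParams:
    """Deadbands proportional to the rest-phase EMG noise floor.

    Pools the second half of every rest phase (well clear of the release
    ramp), takes the per-channel standard deviation, and returns
    ``factor`` times it as both the ZC and SSC deadband.
    """
    rate = recording.sample_rate_hz
    chunks = []
    for ev in recording.events:
        a = int(((ev.contraction_offset_s + ev.rest_offset_s) / 2.0) * rate)
        b = int(ev.rest_offset_s * rate)
        chunks.append(recording.emg[:, a:b])
    rest = np.concatenate(chunks, axis=1)
    sd = rest.std(axis=1)
    return FeatureParams(zc_threshold=factor * sd, ssc_threshold=factor * sd)
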