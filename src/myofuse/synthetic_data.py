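"""Synthetic EMG/FMG session generator.

Emulates a grasp-and-hold experiment in which a participant wearing an
8-channel surface-EMG + 8-channel force-myography (FMG) forearm band grasps
an instrumented object (a 53 g manipulandum, optionally top-loaded with
added weights) with one of four hand gestures, at one of eight reaching
positions, holding for 3 s and resting for 3 s.  Every combination of
gesture x added load x position is performed three times, giving
4 x 5 x 8 x 3 = 480 trials per session.

The signal model is deliberately simple but carries the structure the
downstream feature/classifier stages respond to:

* EMG: zero-mean amplitude-modulated Gaussian noise.  The per-channel
  envelope gain depends on gesture (a 4 x 8 base-amplitude pattern),
  increases monotonically with grasped load, and is perturbed by
  deterministic position- and load-dependent pattern distortions
  (emulating electrode shift and stabiliser co-contraction — the
  "position effect" and load effect).
* FMG: slowly varying non-negative pressure following a first-order lag
  toward a gesture/load/position-dependent contact-pressure target during
  contraction and back toward baseline during rest.  Unequal rise/decay
  time constants give hysteresis; an optional linear drift emulates FSR
  drift error.

All randomness flows through a single integer seed; regenerating with the
same seed and configuration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "GESTURES",
    "LOADS_G",
    "POSITIONS",
    "N_CHANNELS",
    "CONTRACTION_S",
    "REST_S",
    "MANIPULANDUM_SELF_WEIGHT_G",
    "NEUTRAL_POSITION",
    "NEUTRAL_LOAD_G",
    "ConditionLabel",
    "TrialEvent",
    "SessionRecording",
    "SimulationConfig",
    "all_conditions",
    "generate_schedule",
    "position_perturbation",
    "load_perturbation",
    "compute_activation",
    "simulate_session",
    "null_effect_config",
    "split_information_config",
]

GESTURES: tuple[str, ...] = ("key", "pulp_pinch", "power", "tripod")
LOADS_G: tuple[int, ...] = (0, 250, 500, 750, 1000)
POSITIONS: tuple[int, ...] = tuple(range(1, 9))
N_CHANNELS = 8

CONTRACTION_S = 3.0
REST_S = 3.0
#: Self-weight of the graspable object; added loads in LOADS_G come on top.
MANIPULANDUM_SELF_WEIGHT_G = 53

#: Elbow bent at 90 degrees, no added load — the conventional training posture.
NEUTRAL_POSITION = 2
NEUTRAL_LOAD_G = 0


@dataclass(frozen=True)
class ConditionLabel:
    """One of the 160 experimental conditions (gesture, added load, position)."""

    gesture: str
    load_g: int
    position: int

    def __post_init__(self) -> None:
        if self.gesture not in GESTURES:
            raise ValueError(
                f"unknown gesture {self.gesture!r}; expected one of {GESTURES}"
            )
        if self.load_g not in LOADS_G:
            raise ValueError(
                f"unknown load {self.load_g!r} g; expected one of {LOADS_G}"
            )
        if self.position not in POSITIONS:
            raise ValueError(
                f"position {self.position!r} out of range; expected 1..8"
            )

    @property
    def canonical_index(self) -> int:
        """Rank in gesture-major, then load-ascending, then position order."""
        g = GESTURES.index(self.gesture)
        l = LOADS_G.index(self.load_g)
        p = POSITIONS.index(self.position)
        return (g * len(LOADS_G) + l) * len(POSITIONS) + p

    def as_tuple(self) -> tuple[str, int, int]:
        return (self.gesture, self.load_g, self.position)


def all_conditions() -> list[ConditionLabel]:
    """All 160 conditions in canonical order (gesture-major, load, position)."""
    return [
        ConditionLabel(g, l, p) for g in GESTURES for l in LOADS_G for p in POSITIONS
    ]


@dataclass(frozen=True)
class TrialEvent:
    """One grasp-and-release trial: 3 s contraction followed by 3 s rest."""

    condition: ConditionLabel
    repetition: int
    contraction_onset_s: float
    contraction_offset_s: float
    rest_offset_s: float

    def __post_init__(self) -> None:
        if not 1 <= self.repetition <= 3:
            raise ValueError(f"repetition {self.repetition} out of range 1..3")


@dataclass
class SessionRecording:
    """Event-annotated 16-channel recording of one simulated session."""

    sample_rate_hz: float
    emg: np.ndarray  # (8, N), arbitrary voltage units, zero-mean at rest
    fmg: np.ndarray  # (8, N), arbitrary non-negative force units
    events: list[TrialEvent]
    participant_id: str
    rng_seed: int

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.emg.shape[0] != N_CHANNELS or self.fmg.shape[0] != N_CHANNELS:
            raise ValueError(
                f"expected {N_CHANNELS} channels per modality, got "
                f"emg {self.emg.shape[0]}, fmg {self.fmg.shape[0]}"
            )
        if self.emg.shape[1] != self.fmg.shape[1]:
            raise ValueError("emg and fmg must have identical length")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]


# Base envelope gains per (gesture, channel): spatial activation patterns
# for the four grasps, loosely mimicking differing recruitment of flexor/
# extensor compartments under the band.  Units are arbitrary.  The power
# grasp reuses the key pattern scaled up, and tripod reuses pulp pinch
# scaled up: stronger whole-hand grasps recruit the same compartments
# harder.  Because added load also scales amplitude (by up to 1.4x at
# 1000 g with the default slope), a heavily loaded weak grasp can mimic an
# unloaded strong grasp — the mechanism by which load variation genuinely
# confuses gestures, as opposed to merely rescaling them.
_KEY_EMG = np.array([1.20, 0.40, 0.90, 0.30, 0.70, 1.00, 0.35, 0.55])
_PULP_EMG = np.array([0.45, 1.10, 0.35, 0.95, 0.60, 0.40, 1.05, 0.30])
_DEFAULT_EMG_BASE = np.vstack(
    [_KEY_EMG, _PULP_EMG, 1.35 * _KEY_EMG, 1.35 * _PULP_EMG]
)

# Gesture-specific FMG contact-pressure targets (arbitrary force units),
# with the same proportional strong-grasp structure (larger ratio: FMG
# contact pressure saturates less than EMG drive).
_KEY_FMG = np.array([2.4, 0.8, 1.8, 0.6, 1.4, 2.0, 0.7, 1.1])
_PULP_FMG = np.array([0.9, 2.2, 0.7, 1.9, 1.2, 0.8, 2.1, 0.6])
_DEFAULT_FMG_PATTERN = np.vstack(
    [_KEY_FMG, _PULP_FMG, 1.5 * _KEY_FMG, 1.5 * _PULP_FMG]
)


@dataclass
class SimulationConfig:
    """Signal-model parameters for one synthetic participant cohort.

    ``emg_base_amplitude`` and ``fmg_gesture_pattern`` are (4, 8) matrices in
    the canonical gesture order.  ``load_gain_slope`` (per gram, per channel)
    makes envelopes monotone increasing in added load.  ``position_effect``
    and ``load_effect`` scale deterministic channel-pattern perturbations;
    setting both to zero (and drift to zero) makes the 40 load/position cells
    of a gesture distributionally identical.
    """

    sample_rate_hz: float = 2000.0
    emg_base_amplitude: np.ndarray = field(
        default_factory=lambda: _DEFAULT_EMG_BASE.copy()
    )
    load_gain_slope: np.ndarray = field(
        default_factory=lambda: np.full(N_CHANNELS, 4e-4)
    )
    position_effect: float = 0.5  # kappa_pos
    load_effect: float = 0.3  # kappa_load
    fmg_baseline: np.ndarray = field(default_factory=lambda: np.full(N_CHANNELS, 0.5))
    fmg_gesture_pattern: np.ndarray = field(
        default_factory=lambda: _DEFAULT_FMG_PATTERN.copy()
    )
    fmg_rise_tau_s: float = 0.15
    fmg_decay_tau_s: float = 0.25
    fmg_drift_slope: float = 0.0  # units per second
    noise_sd_emg: float = 0.05
    noise_sd_fmg: float = 0.02
    trial_jitter_sd: float = 0.04  # log-SD of per-trial channel gain jitter
    envelope_ramp_s: float = 0.25
    emg_band_hz: tuple[float, float] | None = None  # e.g. (20, 450)

    def __post_init__(self) -> None:
        self.emg_base_amplitude = np.asarray(self.emg_base_amplitude, dtype=float)
        self.load_gain_slope = np.asarray(self.load_gain_slope, dtype=float)
        self.fmg_baseline = np.asarray(self.fmg_baseline, dtype=float)
        self.fmg_gesture_pattern = np.asarray(self.fmg_gesture_pattern, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.emg_base_amplitude.shape != (len(GESTURES), N_CHANNELS):
            raise ValueError("emg_base_amplitude must be 4 x 8")
        if self.fmg_gesture_pattern.shape != (len(GESTURES), N_CHANNELS):
            raise ValueError("fmg_gesture_pattern must be 4 x 8")
        if self.load_gain_slope.shape != (N_CHANNELS,):
            raise ValueError("load_gain_slope must have one entry per channel")
        if self.fmg_baseline.shape != (N_CHANNELS,):
            raise ValueError("fmg_baseline must have one entry per channel")
        for name in (
            "position_effect",
            "load_effect",
            "fmg_rise_tau_s",
            "fmg_decay_tau_s",
            "noise_sd_emg",
            "noise_sd_fmg",
            "trial_jitter_sd",
            "envelope_ramp_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if np.any(self.load_gain_slope < 0):
            raise ValueError("load_gain_slope entries must be >= 0")
        if np.any(self.emg_base_amplitude < 0) or np.any(self.fmg_gesture_pattern < 0):
            raise ValueError("amplitude patterns must be >= 0")
        if np.any(self.fmg_baseline < 0):
            raise ValueError("fmg_baseline must be >= 0")


def null_effect_config(**overrides) -> SimulationConfig:
    """Config with position/load pattern effects and drift disabled.

    Load still scales amplitude through ``load_gain_slope`` unless that is
    also overridden; pass ``load_gain_slope=np.zeros(8)`` for full nullity.
    """
    cfg = SimulationConfig(
        position_effect=0.0, load_effect=0.0, fmg_drift_slope=0.0, **overrides
    )
    return cfg


def split_information_config(**overrides) -> SimulationConfig:
    """Config in which gesture identity is split across modalities.

    EMG envelopes distinguish only {key, pulp_pinch} from {power, tripod};
    FMG targets distinguish only {key, power} from {pulp_pinch, tripod}.
    Either modality alone can separate the four gestures into two pairs at
    best; only the stacked EMG+FMG vector identifies all four.
    """
    pair_a = np.array([1.20, 0.40, 0.90, 0.30, 0.70, 1.00, 0.35, 0.55])
    pair_b = np.array([0.45, 1.10, 0.35, 0.95, 0.60, 0.40, 1.05, 0.30])
    emg = np.vstack([pair_a, pair_a, pair_b, pair_b])
    fmg_a = np.array([2.4, 0.8, 1.8, 0.6, 1.4, 2.0, 0.7, 1.1])
    fmg_b = np.array([0.9, 2.2, 0.7, 1.9, 1.2, 0.8, 2.1, 0.6])
    fmg = np.vstack([fmg_a, fmg_b, fmg_a, fmg_b])
    defaults = dict(
        emg_base_amplitude=emg,
        fmg_gesture_pattern=fmg,
        position_effect=0.0,
        load_effect=0.0,
        fmg_drift_slope=0.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def generate_schedule(seed: int) -> list[TrialEvent]:
    """Randomised trial schedule for one session.

    The protocol nests grasp (outermost), then added load, then position;
    the three repetitions of a condition are consecutive because the object
    stays in place until they are done.  The order of grasps, of loads
    within a grasp, and of positions within a load is permuted by the seeded
    generator.  Trials tile time contiguously at 3 s contraction + 3 s rest.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    events: list[TrialEvent] = []
    t = 0.0
    for g in rng.permutation(len(GESTURES)):
        for l in rng.permutation(len(LOADS_G)):
            for p in rng.permutation(len(POSITIONS)):
                cond = ConditionLabel(GESTURES[g], LOADS_G[l], POSITIONS[p])
                for rep in (1, 2, 3):
                    events.append(
                        TrialEvent(
                            condition=cond,
                            repetition=rep,
                            contraction_onset_s=t,
                            contraction_offset_s=t + CONTRACTION_S,
                            rest_offset_s=t + CONTRACTION_S + REST_S,
                        )
                    )
                    t += CONTRACTION_S + REST_S
    return events


def position_perturbation(position: int, n_channels: int = N_CHANNELS) -> np.ndarray:
    """Deterministic per-channel pattern distortion for a reaching position.

    A unit-amplitude sinusoid over the channel ring whose phase advances
    with position, emulating a consistent rotation/shift of the activation
    pattern as the arm moves.  Values lie in [-1, 1]; seed-independent.
    """
    if position not in POSITIONS:
        raise ValueError(f"position {position!r} out of range; expected 1..8")
    c = np.arange(n_channels)
    phase = 2.0 * np.pi * (position - 1) / len(POSITIONS)
    return np.sin(2.0 * np.pi * c / n_channels + phase)


def load_perturbation(load_g: int, n_channels: int = N_CHANNELS) -> np.ndarray:
    """Deterministic pattern distortion for an added load, in [-1, 1].

    The constant phase offset is chosen so that, relative to the neutral
    training cell, the heavy-load distortion acts along a channel
    direction positively correlated with the outstretched-position
    distortion: moving far in position AND load compounds the pattern
    mismatch instead of letting the two sinusoids cancel.
    """
    if load_g not in LOADS_G:
        raise ValueError(f"unknown load {load_g!r} g; expected one of {LOADS_G}")
    c = np.arange(n_channels)
    phase = 2.0 * np.pi * LOADS_G.index(load_g) / len(LOADS_G)
    return np.sin(2.0 * np.pi * c / n_channels + phase - 0.175 * np.pi)


def compute_activation(
    condition: ConditionLabel, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel EMG envelope gains and FMG pressure targets for a condition.

    EMG gain on channel c:

        base[gesture, c] * (1 + slope_c * load_g)
                         * (1 + k_pos * d_pos(position, c)
                              + k_load * d_load(load_g, c))

    clipped at zero.  The FMG target is baseline + the gesture contact
    pattern under the same load scaling and pattern distortion, clipped at
    zero.  ``d_pos`` / ``d_load`` are the fixed perturbation tables.
    """
    config.validate()
    g = GESTURES.index(condition.gesture)
    d_pos = position_perturbation(condition.position)
    d_load = load_perturbation(condition.load_g)
    distort = 1.0 + config.position_effect * d_pos + config.load_effect * d_load
    load_gain = 1.0 + config.load_gain_slope * condition.load_g

    emg_gain = np.clip(config.emg_base_amplitude[g] * load_gain * distort, 0.0, None)
    fmg_target = np.clip(
        config.fmg_baseline + config.fmg_gesture_pattern[g] * load_gain * distort,
        0.0,
        None,
    )
    return emg_gain, fmg_target


def _envelope(
    n: int, onset_idx: int, offset_idx: int, ramp_samples: int
) -> np.ndarray:
    """Trapezoidal 0->1->0 contraction envelope over sample indices."""
    idx = np.arange(onset_idx, offset_idx)
    if ramp_samples == 0:
        return np.ones(idx.size)
    up = (idx - onset_idx) / ramp_samples
    down = (offset_idx - idx) / ramp_samples
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def _bandlimited_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    band_hz: tuple[float, float] | None,
    rate: float,
) -> np.ndarray:
    """Unit-variance Gaussian carrier, optionally band-limited.

    Band-limiting uses a 4th-order Butterworth band-pass applied forward-
    backward (zero phase), then re-normalised to unit variance per channel.
    """
    w = rng.standard_normal(shape, dtype=np.float32)
    if band_hz is None:
        return w
    lo, hi = band_hz
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    w = _sig.sosfiltfilt(sos, w, axis=1)
    w /= w.std(axis=1, keepdims=True)
    return np.ascontiguousarray(w, dtype=np.float32)


def simulate_session(
    schedule: Sequence[TrialEvent],
    config: SimulationConfig,
    participant_id: str,
    seed: int,
) -> SessionRecording:
    """Simulate one 16-channel session for the given trial schedule.

    EMG channel c is ``(noise_floor + envelope(t) * gain_c) * w_c(t)`` with
    ``w`` a unit-variance Gaussian carrier and a trapezoidal envelope
    ramping over ``envelope_ramp_s`` at contraction onset/offset; at rest
    the amplitude is the ``noise_sd_emg`` floor alone.  FMG channel c
    relaxes exponentially toward its condition target during contraction
    (time constant ``fmg_rise_tau_s``) and toward baseline during rest
    (``fmg_decay_tau_s``), then linear drift and Gaussian sensor noise are
    added and the result is clipped at zero.

    ``trial_jitter_sd`` applies an independent per-trial, per-channel
    log-normal gain jitter to the EMG envelope and to the FMG target's
    excursion above baseline, emulating trial-to-trial variability in
    contraction intensity and sensor coupling.  Set it to zero for a
    noiseless-envelope model in which repeated trials of a condition are
    exact repeats up to carrier noise.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    config.validate()
    rate = config.sample_rate_hz
    n = int(round(schedule[-1].rest_offset_s * rate))
    rng = np.random.default_rng(seed)

    # Signals are synthesised in float32: the downstream features operate
    # far above that precision and the arrays are large (16 x 5.76 M
    # samples for a full 480-trial session).
    emg_carrier = _bandlimited_noise(rng, (N_CHANNELS, n), config.emg_band_hz, rate)
    fmg_noise = rng.standard_normal((N_CHANNELS, n), dtype=np.float32)
    fmg_noise *= np.float32(config.noise_sd_fmg)

    amplitude = np.full((N_CHANNELS, n), config.noise_sd_emg, dtype=np.float32)
    fmg_clean = np.empty((N_CHANNELS, n), dtype=np.float32)

    ramp_samples = int(round(config.envelope_ramp_s * rate))
    dt = 1.0 / rate
    state = config.fmg_baseline.copy()

    for ev in schedule:
        i0 = int(np.floor(ev.contraction_onset_s * rate))
        i1 = int(np.floor(ev.contraction_offset_s * rate))
        i2 = int(np.floor(ev.rest_offset_s * rate))
        if i2 > n or i0 < 0:
            raise ValueError("event lies outside the recording")
        emg_gain, fmg_target = compute_activation(ev.condition, config)
        if config.trial_jitter_sd > 0:
            # trial-to-trial variability: per-channel multiplicative
            # log-normal gain jitter, drawn independently per modality
            emg_gain = emg_gain * np.exp(
                rng.normal(0.0, config.trial_jitter_sd, N_CHANNELS)
            )
            fmg_target = config.fmg_baseline + (
                fmg_target - config.fmg_baseline
            ) * np.exp(rng.normal(0.0, config.trial_jitter_sd, N_CHANNELS))

        env = _envelope(n, i0, i1, ramp_samples).astype(np.float32)
        amplitude[:, i0:i1] += env[None, :] * emg_gain[:, None].astype(np.float32)

        # first-order lag, exact per-sample exponential update
        for (a, b, target, tau) in (
            (i0, i1, fmg_target, config.fmg_rise_tau_s),
            (i1, i2, config.fmg_baseline, config.fmg_decay_tau_s),
        ):
            m = b - a
            if m <= 0:
                continue
            if tau == 0:
                fmg_clean[:, a:b] = target[:, None]
            else:
                decay = np.exp(-dt * np.arange(1, m + 1) / tau)
                fmg_clean[:, a:b] = (
                    target[:, None] + (state - target)[:, None] * decay[None, :]
                )
            state = fmg_clean[:, b - 1].copy()

    emg = amplitude
    emg *= emg_carrier
    fmg = fmg_clean
    fmg += fmg_noise
    if config.fmg_drift_slope != 0.0:
        t = (np.arange(n) * dt).astype(np.float32)
        fmg += np.float32(config.fmg_drift_slope) * t[None, :]
    np.clip(fmg, 0.0, None, out=fmg)

    return SessionRecording(
        sample_rate_hz=rate,
        emg=emg,
        fmg=fmg,
        events=list(schedule),
        participant_id=participant_id,
        rng_seed=seed,
    )
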