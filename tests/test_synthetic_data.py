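"""Generator contracts: schedule combinatorics, activation model, signals."""

import numpy as np
import pytest
from scipy import stats as sps

from myofuse.features import FeatureParams, feature_table, modality_columns
from myofuse.segmentation import SegmentationParams
from myofuse.synthetic_data import (
    GESTURES,
    LOADS_G,
    POSITIONS,
    ConditionLabel,
    SimulationConfig,
    all_conditions,
    compute_activation,
    generate_schedule,
    load_perturbation,
    null_effect_config,
    position_perturbation,
    simulate_session,
)

from conftest import make_schedule


class TestConditionLabel:
    def test_exactly_160_conditions_in_canonical_order(self):
        conds = all_conditions()
        assert len(conds) == 4 * 5 * 8
        assert len(set(conds)) == 160
        assert [c.canonical_index for c in conds] == list(range(160))
        # gesture-major, then load ascending, then position 1..8
        assert conds[0].as_tuple() == ("key", 0, 1)
        assert conds[7].as_tuple() == ("key", 0, 8)
        assert conds[8].as_tuple() == ("key", 250, 1)
        assert conds[40].as_tuple() == ("pulp_pinch", 0, 1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gesture": "fist", "load_g": 0, "position": 1},
            {"gesture": "key", "load_g": 100, "position": 1},
            {"gesture": "key", "load_g": 0, "position": 9},
        ],
    )
    def test_invalid_labels_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ConditionLabel(**kwargs)


class TestSchedule:
    def test_480_trials_each_condition_three_times(self):
        events = generate_schedule(0)
        assert len(events) == 480
        per_cond = {}
        for ev in events:
            per_cond.setdefault(ev.condition, []).append(ev.repetition)
        assert len(per_cond) == 160
        assert all(sorted(reps) == [1, 2, 3] for reps in per_cond.values())

    def test_repetitions_consecutive_and_timestamps_tile(self):
        events = generate_schedule(3)
        t = 0.0
        for ev in events:
            assert ev.contraction_onset_s == pytest.approx(t)
            assert ev.contraction_offset_s - ev.contraction_onset_s == pytest.approx(3.0)
            assert ev.rest_offset_s - ev.contraction_offset_s == pytest.approx(3.0)
            t = ev.rest_offset_s
        # the three repetitions of each condition are adjacent
        for i in range(0, 480, 3):
            block = events[i : i + 3]
            assert len({ev.condition for ev in block}) == 1
            assert [ev.repetition for ev in block] == [1, 2, 3]

    def test_seeded_determinism_and_seed_variation(self):
        a = generate_schedule(0)
        b = generate_schedule(0)
        assert a == b
        c = generate_schedule(1)
        key = lambda ev: (ev.condition.canonical_index, ev.repetition)
        assert sorted(map(key, a)) == sorted(map(key, c))  # same multiset
        assert [ev.condition for ev in a] != [ev.condition for ev in c]

    def test_negative_seed_rejected(self):
        with pytest.raises(ValueError):
            generate_schedule(-1)


class TestActivation:
    def test_effects_disabled_positions_indistinguishable(self):
        cfg = null_effect_config()
        for load in LOADS_G:
            ref_e, ref_f = compute_activation(ConditionLabel("power", load, 1), cfg)
            for pos in POSITIONS[1:]:
                e, f = compute_activation(ConditionLabel("power", load, pos), cfg)
                np.testing.assert_array_equal(e, ref_e)
                np.testing.assert_array_equal(f, ref_f)

    def test_load_monotone_when_slope_positive(self):
        cfg = null_effect_config()
        lo_e, lo_f = compute_activation(ConditionLabel("key", 0, 3), cfg)
        hi_e, hi_f = compute_activation(ConditionLabel("key", 1000, 3), cfg)
        assert np.all(hi_e > lo_e)
        assert np.all(hi_f > lo_f)

    def test_matches_hand_evaluated_formula(self):
        """Independent re-evaluation of the stated gain formula."""
        base = np.arange(1, 9, dtype=float).reshape(1, 8) / 4.0
        base = np.vstack([base, 2 * base, 3 * base, 4 * base])
        cfg = SimulationConfig(
            emg_base_amplitude=base,
            load_gain_slope=np.full(8, 2e-4),
            position_effect=0.3,
            load_effect=0.2,
            fmg_baseline=np.full(8, 0.1),
            fmg_gesture_pattern=base,
        )
        cond = ConditionLabel("pulp_pinch", 500, 4)
        emg, fmg = compute_activation(cond, cfg)
        c = np.arange(8)
        d_pos = np.sin(2 * np.pi * c / 8 + 2 * np.pi * 3 / 8)
        d_load = np.sin(2 * np.pi * c / 8 + 2 * np.pi * 2 / 5 - 0.175 * np.pi)
        expected = base[1] * (1 + 2e-4 * 500) * (1 + 0.3 * d_pos + 0.2 * d_load)
        np.testing.assert_allclose(emg, np.clip(expected, 0, None), rtol=1e-12)
        np.testing.assert_allclose(
            fmg, np.clip(0.1 + expected, 0, None), rtol=1e-12
        )

    def test_perturbation_tables_bounded_and_fixed(self):
        for pos in POSITIONS:
            assert np.all(np.abs(position_perturbation(pos)) <= 1.0)
        for load in LOADS_G:
            assert np.all(np.abs(load_perturbation(load)) <= 1.0)
        np.testing.assert_array_equal(
            position_perturbation(5), position_perturbation(5)
        )


class TestSimulateSession:
    def test_same_seed_bit_identical(self):
        sched = make_schedule([ConditionLabel("key", 0, 2)])
        cfg = SimulationConfig()
        a = simulate_session(sched, cfg, "P00", 7)
        b = simulate_session(sched, cfg, "P00", 7)
        np.testing.assert_array_equal(a.emg, b.emg)
        np.testing.assert_array_equal(a.fmg, b.fmg)
        assert a.events == b.events

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_session([], SimulationConfig(), "P00", 0)

    def test_fmg_reaches_target_within_lag_tolerance(self):
        """Noise-free FMG approaches the first-order-lag closed form."""
        cond = ConditionLabel("power", 0, 2)
        cfg = SimulationConfig(
            noise_sd_emg=0.0,
            noise_sd_fmg=0.0,
            trial_jitter_sd=0.0,
            fmg_drift_slope=0.0,
        )
        rec = simulate_session(make_schedule([cond], reps=1), cfg, "P00", 0)
        _, target = compute_activation(cond, cfg)
        mid = int(1.5 * cfg.sample_rate_hz)
        tol = np.abs(cfg.fmg_baseline - target) * np.exp(-1.5 / cfg.fmg_rise_tau_s)
        assert np.all(np.abs(rec.fmg[:, mid] - target) <= tol + 1e-4)

    def test_fmg_non_negative_even_with_heavy_noise(self):
        cfg = SimulationConfig(noise_sd_fmg=5.0)
        rec = simulate_session(
            make_schedule([ConditionLabel("key", 0, 1)]), cfg, "P00", 3
        )
        assert rec.fmg.min() >= 0.0

    def test_emg_amplitude_monotone_in_load(self):
        """Mid-contraction |EMG| is larger at 1000 g than 0 g on every channel."""
        conds = [ConditionLabel("key", 0, 2), ConditionLabel("key", 1000, 2)]
        cfg = null_effect_config(trial_jitter_sd=0.0)
        rate = int(cfg.sample_rate_hz)
        lo = np.zeros(8)
        hi = np.zeros(8)
        for seed in range(10):
            rec = simulate_session(make_schedule(conds, reps=1), cfg, "P", seed)
            lo += np.abs(rec.emg[:, rate : 2 * rate]).mean(axis=1)
            hi += np.abs(rec.emg[:, 7 * rate : 8 * rate]).mean(axis=1)
        assert np.all(hi > lo)

    def test_channel_counts_and_length(self):
        sched = make_schedule([ConditionLabel("tripod", 250, 6)])
        rec = simulate_session(sched, SimulationConfig(), "P00", 0)
        assert rec.emg.shape == rec.fmg.shape == (8, int(18.0 * 2000))


class TestEffectNullability:
    def test_mav_distribution_identical_across_positions(self):
        """With effects off, positions differ only by sampling noise."""
        cfg = null_effect_config(
            load_gain_slope=np.zeros(8), trial_jitter_sd=0.0
        )
        conds = [ConditionLabel("power", 0, 1), ConditionLabel("power", 0, 5)]
        # 3 reps x 39 windows = 117 windows per position; compare >= 100
        rec = simulate_session(make_schedule(conds), cfg, "P00", 11)
        table = feature_table(rec)
        col = modality_columns("emg")[0]
        a = table.loc[table["position"] == 1, col].to_numpy()
        b = table.loc[table["position"] == 5, col].to_numpy()
        assert min(a.size, b.size) >= 100
        assert sps.ks_2samp(a, b).pvalue > 0.01
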