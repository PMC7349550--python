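"""Generator contracts: degenerate cases, event statistics, determinism
and ground-truth bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest
from numpy.random import default_rng
from scipy import signal as sp_signal

from physioemo.synthio import (CohortSpec, EcgParams, EdaParams, EmgParams,
                               generate_cohort, generate_ecg, generate_eda,
                               generate_emg, load_session_csv,
                               save_session_csv, scaled_down_spec)


class TestEcg:
    def test_degenerate_no_variability_beat_train(self):
        p = EcgParams(mean_hr_bpm=60.0, a_lf_s=0, a_hf_s=0, rr_jitter_s=0,
                      noise_mv=0)
        _, r = generate_ecg(p, 60.0, 1000.0, default_rng(0))
        assert abs(len(r) - 60) <= 1
        np.testing.assert_allclose(np.diff(r), 1.0, atol=1e-9)

    def test_hf_modulation_dominates_rr_spectrum(self):
        p = EcgParams(mean_hr_bpm=75.0, a_hf_s=0.03, a_lf_s=0,
                      rr_jitter_s=0, noise_mv=0)
        _, r = generate_ecg(p, 300.0, 1000.0, default_rng(1))
        rr = np.diff(r)
        freqs = np.linspace(0.02, 0.45, 200)
        pg = sp_signal.lombscargle(r[1:], rr - rr.mean(), 2 * np.pi * freqs)
        assert freqs[np.argmax(pg)] == pytest.approx(0.25, abs=0.02)

    def test_same_seed_bit_identical(self):
        p = EcgParams(mean_hr_bpm=70.0, t_jitter_mv=0.02)
        x1, r1 = generate_ecg(p, 30.0, 1000.0, default_rng(7))
        x2, r2 = generate_ecg(p, 30.0, 1000.0, default_rng(7))
        assert np.array_equal(x1, x2) and np.array_equal(r1, r2)

    def test_rejects_out_of_range_hr_and_bad_duration(self):
        with pytest.raises(ValueError):
            generate_ecg(EcgParams(mean_hr_bpm=250.0), 10, 1000, default_rng(0))
        with pytest.raises(ValueError):
            generate_ecg(EcgParams(mean_hr_bpm=60.0), -5, 1000, default_rng(0))


class TestEda:
    def test_zero_rate_flat_tonic_constant(self):
        p = EdaParams(tonic_us=2.0, scr_rate_per_min=0.0, tonic_drift_us=0.0,
                      noise_us=0.0)
        x, events = generate_eda(p, 30.0, 1000.0, default_rng(0))
        assert events.size == 0
        np.testing.assert_allclose(x, 2.0, atol=1e-12)

    def test_poisson_event_count_within_95_band(self):
        # rate 4/min over 300 s -> mean 20; average over seeds must fall
        # inside the 95% CI of the mean of n Poisson(20) draws
        n_seeds, lam = 40, 20.0
        counts = [generate_eda(EdaParams(2.0, 4.0), 300.0, 1000.0,
                               default_rng(s))[1].size
                  for s in range(n_seeds)]
        half = 1.96 * np.sqrt(lam / n_seeds)
        assert abs(np.mean(counts) - lam) < half

    def test_hotspot_concentrates_events(self):
        p = EdaParams(2.0, 4.0, hotspot=(60.0, 180.0), hotspot_factor=3.0)
        inside = outside = 0.0
        for s in range(20):
            ev = generate_eda(p, 300.0, 1000.0, default_rng(s))[1]
            inside += np.sum((ev >= 60) & (ev < 180)) / 120.0
            outside += np.sum((ev < 60) | (ev >= 180)) / 180.0
        assert inside > 2.0 * outside


class TestEmg:
    def test_zero_rate_envelope_stationary(self):
        x, bursts = generate_emg(EmgParams(0.0), 30.0, 1000.0, default_rng(0))
        assert len(bursts) == 0
        env = np.abs(x)
        halves = env[:15000].mean(), env[15000:].mean()
        assert abs(halves[0] - halves[1]) / halves[0] < 0.1

    def test_planted_bursts_exceed_baseline_exactly_where_planted(self):
        from physioemo.featx import emg_envelope
        x, bursts = generate_emg(
            EmgParams(5.0, burst_amp_factor=10.0, burst_len_s=0.6),
            120.0, 1000.0, default_rng(3))
        env = emg_envelope(x, 1000.0)
        base = np.median(env)
        hot = env > 3.0 * base
        for a, b in bursts:
            mid = int((a + b) / 2 * 1000)
            assert hot[mid]
        # outside any burst (with margin) the envelope stays below 3x median
        mask = np.zeros(x.size, dtype=bool)
        for a, b in bursts:
            mask[int((a - 0.3) * 1000):int((b + 0.3) * 1000)] = True
        assert not hot[~mask].any()

    def test_happy_zygomatic_exceeds_frontalis_by_construction(self):
        z_total = mf_total = 0
        for s in range(6):
            spec = scaled_down_spec(n_subjects=1, conditions=("happy",),
                                    seed=s)
            gt = generate_cohort(spec)[0].ground_truth
            z_total += len(gt.emg_burst_intervals["emg_z"])
            mf_total += len(gt.emg_burst_intervals["emg_mf"])
        assert z_total > mf_total


class TestCohort:
    def test_shape_and_shared_subject_parameters(self):
        spec = scaled_down_spec(n_subjects=2, session_minutes=6.0,
                                hotspot_start_s=30.0, seed=5)
        sessions = generate_cohort(spec)
        assert len(sessions) == 6
        by_subject = {}
        for s in sessions:
            by_subject.setdefault(s.subject_id, []).append(
                s.ground_truth.params["subject_offsets"])
        for offs in by_subject.values():
            assert all(o == offs[0] for o in offs)

    def test_channel_lag_shifts_hotspot_ground_truth(self):
        spec = scaled_down_spec(n_subjects=1, seed=0,
                                channel_lags_s={"eda": 7})
        gt = generate_cohort(spec)[0].ground_truth
        assert gt.hotspot["eda"][0] - gt.hotspot["ecg"][0] == 7
        for ch, (a, b) in gt.hotspot.items():
            assert b - a == spec.hotspot_len_s

    def test_same_seed_reproducible_checksum(self):
        spec = scaled_down_spec(n_subjects=1, session_minutes=6.0,
                                hotspot_start_s=30.0, seed=9)
        s1 = generate_cohort(spec)
        s2 = generate_cohort(spec)
        for a, b in zip(s1, s2):
            for ch in a.channels:
                assert np.array_equal(a.channels[ch], b.channels[ch])

    def test_condition_hr_effect_is_monotone_pass_through(self):
        # doubling the fear-neutral HR offset doubles the measured mean HR
        # difference on generated R-peak times (within jitter tolerance)
        from physioemo.synthio import DEFAULT_EFFECTS
        import dataclasses

        def measured_diff(fear_hr):
            effects = dict(DEFAULT_EFFECTS)
            effects["fear"] = dataclasses.replace(effects["fear"],
                                                  hr_bpm=fear_hr)
            spec = scaled_down_spec(n_subjects=2, session_minutes=6.0,
                                    hotspot_start_s=30.0, seed=21,
                                    arousal_amplitude=0.0,
                                    hotspot_factor=1.0, effects=effects)
            hr = {"fear": [], "neutral": []}
            for s in generate_cohort(spec):
                if s.condition in hr:
                    rr = np.diff(s.ground_truth.r_peak_times)
                    hr[s.condition].append(60.0 / rr.mean())
            return np.mean(hr["fear"]) - np.mean(hr["neutral"])

        base = DEFAULT_EFFECTS["neutral"].hr_bpm
        offset = DEFAULT_EFFECTS["fear"].hr_bpm - base
        d1 = measured_diff(base + offset)
        d2 = measured_diff(base + 2 * offset)
        assert d2 == pytest.approx(2 * d1, rel=0.15)

    def test_ground_truth_events_inside_session(self):
        spec = scaled_down_spec(n_subjects=1, seed=4)
        for s in generate_cohort(spec):
            gt = s.ground_truth
            assert np.all(np.diff(gt.r_peak_times) > 0)
            assert gt.r_peak_times[-1] <= s.duration_s
            if gt.scr_event_times.size:
                assert gt.scr_event_times[0] >= 0
                assert gt.scr_event_times[-1] <= s.duration_s
            for ivs in gt.emg_burst_intervals.values():
                for a, b in ivs:
                    assert 0 <= a < b <= s.duration_s

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(session_minutes=4.0, hotspot_len_s=300.0,
                       hotspot_start_s=0.0)
        with pytest.raises(ValueError):
            CohortSpec(hotspot_start_s=2000.0)
        with pytest.raises(ValueError):
            scaled_down_spec(channel_lags_s={"bogus": 3})


def test_session_csv_roundtrip(tmp_path):
    spec = scaled_down_spec(n_subjects=1, session_minutes=1.0,
                            hotspot_start_s=5.0, hotspot_len_s=30.0, seed=2)
    s = generate_cohort(spec)[0]
    path = tmp_path / "sess.csv"
    save_session_csv(s, path)
    loaded = load_session_csv(path)
    assert loaded.subject_id == s.subject_id
    assert loaded.condition == s.condition
    for ch in s.channels:
        np.testing.assert_allclose(loaded.channels[ch], s.channels[ch],
                                   atol=1e-5)
    np.testing.assert_allclose(loaded.ground_truth.r_peak_times,
                               s.ground_truth.r_peak_times)
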