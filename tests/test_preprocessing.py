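"""Filtering, beat detection, epoching, quality screening and alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgabp.preprocessing import (
    Epoch,
    align_epoch,
    bandpass_filter,
    classify_by_sbp,
    detect_systolic_peaks,
    normalize,
    preprocess_record,
    quality_screen,
    segment_epochs,
)
from ppgabp.synthetic import (
    WaveformRecord,
    derive_ppg_from_abp,
    generate_pulse_train,
)
from ppgabp.timedomain import pearson_r

FS = 125.0


class TestBandpass:
    def test_in_band_tone_preserved(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = bandpass_filter(x, FS)
        mid = slice(500, -500)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.05)

    def test_dc_rejected(self):
        y = bandpass_filter(np.full(2000, 7.3), FS)
        assert np.max(np.abs(y)) < 1e-6

    def test_out_of_band_tone_attenuated_20db(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 30.0 * t)
        y = bandpass_filter(x, FS)
        assert np.max(np.abs(y[500:-500])) < 0.1  # >= 20 dB down

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), fs=25.0)


class TestNormalize:
    def test_moments_and_idempotence(self):
        x = np.array([1.0, 2.0, 3.0])
        z = normalize(x)
        assert abs(z.mean()) < 1e-12 and z.std() == pytest.approx(1.0)
        assert np.allclose(normalize(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.ones(10))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mean_always_vanishes(self, seed):
        x = np.random.default_rng(seed).normal(3.0, 5.0, size=200)
        assert abs(normalize(x).mean()) < 1e-12

    def test_filter_normalize_commutes_on_zero_mean_input(self):
        rng = np.random.default_rng(0)
        x = bandpass_filter(rng.standard_normal(4000), FS)  # zero-mean input
        a = normalize(bandpass_filter(normalize(x), FS))
        b = normalize(bandpass_filter(x, FS))
        assert np.allclose(a, b, atol=1e-10)


class TestPeakDetection:
    def test_clean_train_counts_and_intervals(self):
        x = generate_pulse_train(60, 120, 80, duration_s=120, jitter=0.0, seed=0)
        peaks = detect_systolic_peaks(bandpass_filter(x, FS), FS)
        assert 119 <= peaks.size <= 121
        assert np.all(np.abs(np.diff(peaks) - FS) <= 1)

    def test_flat_signal_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no peaks"):
            peaks = detect_systolic_peaks(np.zeros(1000), FS)
        assert peaks.size == 0

    @pytest.mark.parametrize("hr", [50, 70, 90, 120])
    def test_recall_precision_on_noise_free_trains(self, hr):
        x, truth, _ = generate_pulse_train(
            hr, 120, 80, duration_s=60, jitter=0.02, seed=hr, return_beats=True
        )
        peaks = detect_systolic_peaks(bandpass_filter(x, FS), FS)
        tol = int(0.04 * FS)
        matched = sum(np.min(np.abs(peaks - t)) <= tol for t in truth)
        assert matched / truth.size >= 0.99
        false_pos = sum(np.min(np.abs(truth - p)) > tol for p in peaks)
        assert false_pos / peaks.size <= 0.01

    def test_recall_under_noise(self):
        """>= 99% of true beats recovered within 40 ms at 20 dB SNR."""
        x, truth, _ = generate_pulse_train(
            75, 120, 80, duration_s=120, jitter=0.03, seed=3, return_beats=True
        )
        noisy = x + 0.1 * np.std(x) * np.random.default_rng(7).standard_normal(x.size)
        peaks = detect_systolic_peaks(bandpass_filter(noisy, FS), FS)
        tol = int(0.04 * FS)
        matched = sum(np.min(np.abs(peaks - t)) <= tol for t in truth)
        assert matched / truth.size >= 0.99


def _segmented(duration=120.0, hr=60, seed=0):
    abp = generate_pulse_train(hr, 120, 80, duration_s=duration, jitter=0.02,
                               seed=seed)
    ppg = derive_ppg_from_abp(abp, FS, delay_ms=200)
    abp_f = normalize(bandpass_filter(abp, FS))
    ppg_f = normalize(bandpass_filter(ppg, FS))
    a_pk = detect_systolic_peaks(abp_f, FS)
    p_pk = detect_systolic_peaks(ppg_f, FS)
    return segment_epochs(abp_f, ppg_f, FS, a_pk, p_pk, subject_id="s")


class TestSegmentation:
    def test_epoch_count_at_60_bpm(self):
        epochs = _segmented()
        assert 11 <= len(epochs) <= 12
        for ep in epochs:
            assert ep.beat_indices_abp.size == 10

    def test_too_few_beats_gives_empty(self):
        x = np.zeros(1000)
        with pytest.warns(UserWarning, match="beats"):
            out = segment_epochs(x, x, FS, np.arange(9) * 100, np.arange(9) * 100)
        assert out == []

    def test_epochs_are_a_partition(self):
        epochs = _segmented()
        spans = [(ep.start, ep.start + ep.n_samples) for ep in epochs]
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            assert a1 == b0  # contiguous, non-overlapping
        assert spans[0][0] >= 0


class TestQualityScreen:
    def test_clean_epoch_passes(self, small_epochs):
        assert len(small_epochs) > 50  # screening keeps the bulk of clean data

    def test_zeroed_channel_fails(self):
        epochs = _segmented()
        ep = epochs[2]
        ep.ppg[100 : 100 + int(2 * FS)] = 0.0
        ep.beat_indices_ppg = ep.beat_indices_ppg[:4]
        assert quality_screen(ep) is False

    def test_sensitivity_to_injected_artifacts(self):
        """>= 90% of artifact-bearing epochs are flagged."""
        rng = np.random.default_rng(5)
        epochs = []
        for seed in range(18):
            epochs.extend(_segmented(duration=120, hr=72, seed=seed))
        epochs = epochs[:200]
        injected = rng.choice(len(epochs), size=20, replace=False)
        for k, idx in enumerate(injected):
            ep = epochs[idx]
            if k % 2 == 0:
                a = int(rng.integers(0, ep.n_samples - int(2 * FS)))
                ep.ppg[a : a + int(2 * FS)] = ep.ppg[a]  # saturation dropout
            else:
                pk = ep.beat_indices_abp[5]
                ep.abp[max(0, pk - 10) : pk + 10] += 8.0  # amplitude spike
        flagged = [not quality_screen(ep) for ep in epochs]
        sensitivity = np.mean([flagged[i] for i in injected])
        assert sensitivity >= 0.9


class TestAlignment:
    def test_pure_delay_recovered(self):
        abp = generate_pulse_train(70, 120, 80, duration_s=30, jitter=0.0, seed=1)
        abp_f = normalize(bandpass_filter(abp, FS))
        ppg_f = np.roll(abp_f, 25)
        a_pk = detect_systolic_peaks(abp_f, FS)
        p_pk = detect_systolic_peaks(ppg_f, FS)
        epochs = segment_epochs(abp_f, ppg_f, FS, a_pk, p_pk)
        ep = align_epoch(epochs[1])
        assert ep.alignment_shift == 25
        assert pearson_r(ep.abp, ep.ppg) > 1 - 1e-6

    def test_zero_delay_keeps_zero_shift(self):
        abp = generate_pulse_train(70, 120, 80, duration_s=30, jitter=0.0, seed=2)
        abp_f = normalize(bandpass_filter(abp, FS))
        a_pk = detect_systolic_peaks(abp_f, FS)
        epochs = segment_epochs(abp_f, abp_f, FS, a_pk, a_pk)
        assert align_epoch(epochs[1]).alignment_shift == 0

    def test_alignment_never_decreases_correlation(self, small_epochs):
        for ep in small_epochs:
            aligned = align_epoch(ep)
            if not aligned.quality_ok:
                continue
            assert pearson_r(aligned.abp, aligned.ppg) >= pearson_r(
                ep.abp, ep.ppg
            ) - 1e-12


class TestSBPClassification:
    @pytest.mark.parametrize(
        "sbp,expected", [(119.0, "NT"), (120.5, "PHT"), (140.5, "HT")]
    )
    def test_band_boundaries(self, sbp, expected):
        x = generate_pulse_train(70, sbp, sbp - 40, duration_s=30, jitter=0.0,
                                 amplitude_jitter_mmHg=0.0, seed=0)
        rec = WaveformRecord("s", FS, x, x - x.mean(), truth=None)
        assert classify_by_sbp(rec) == expected

    def test_cohort_labels_recovered(self, small_cohort):
        hits = sum(
            classify_by_sbp(rec) == rec.truth["group"] for rec in small_cohort
        )
        assert hits >= 0.95 * len(small_cohort)


def test_preprocess_record_pipeline(small_cohort):
    epochs, info = preprocess_record(small_cohort[0])
    assert info["group"] == small_cohort[0].truth["group"]
    assert info["n_epochs"] == len(epochs)
    assert info["n_quality_ok"] >= 1
    for ep in epochs:
        assert ep.abp.size == ep.ppg.size
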