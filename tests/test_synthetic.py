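"""Generator correctness: VAR simulation, pulse trains, PPG coupling, cohorts."""

import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov

from ppgabp.preprocessing import classify_by_sbp
from ppgabp.synthetic import (
    CohortSpec,
    VARSpec,
    WaveformRecord,
    companion_matrix,
    derive_ppg_from_abp,
    generate_cohort,
    generate_pulse_train,
    simulate_var,
)
from ppgabp.timedomain import pearson_r

UNIDIR = np.array([[[0.5, 0.0], [0.7, 0.5]]])  # channel 1 drives channel 2


class TestVARSpec:
    def test_rejects_nonstationary_with_radius_diagnostic(self):
        coeffs = np.array([[[1.01, 0.0], [0.0, 0.5]]])
        with pytest.raises(ValueError, match="spectral radius"):
            VARSpec(order=1, coeffs=coeffs, noise_cov=np.eye(2))

    def test_rejects_indefinite_noise_cov(self):
        with pytest.raises(ValueError, match="positive definite"):
            VARSpec(order=1, coeffs=np.zeros((1, 2, 2)),
                    noise_cov=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_accepted_specs_are_stationary(self):
        """Every accepted random spec has companion spectral radius < 1."""
        rng = np.random.default_rng(0)
        accepted = 0
        while accepted < 100:
            p = int(rng.integers(1, 4))
            coeffs = rng.normal(0, 0.3, size=(p, 2, 2))
            try:
                spec = VARSpec(order=p, coeffs=coeffs, noise_cov=np.eye(2))
            except ValueError:
                continue
            assert spec.spectral_radius < 1.0
            accepted += 1


class TestSimulateVar:
    def test_no_dynamics_gives_uncorrelated_white_noise(self):
        spec = VARSpec(order=1, coeffs=np.zeros((1, 2, 2)), noise_cov=np.eye(2))
        x = simulate_var(spec, n=100_000, seed=5)
        n = x.shape[0]
        bound = 4.0 / np.sqrt(n)
        for lag in range(4):
            a = x[lag:, 0] - x[:, 0].mean()
            b = x[: n - lag, 1] - x[:, 1].mean()
            assert abs(np.mean(a * b)) < bound

    def test_lag_one_cross_covariance_matches_lyapunov_solution(self):
        """Sample cov(Y_t, X_{t-1}) agrees with the closed-form stationary value."""
        A = UNIDIR[0]
        spec = VARSpec(order=1, coeffs=UNIDIR, noise_cov=np.eye(2))
        gamma0 = solve_discrete_lyapunov(A, np.eye(2))
        expected = (A @ gamma0)[1, 0]  # E[x_t x_{t-1}^T], element (Y, X)
        x = simulate_var(spec, n=300_000, seed=9)
        sample = np.mean(
            (x[1:, 1] - x[:, 1].mean()) * (x[:-1, 0] - x[:, 0].mean())
        )
        assert sample == pytest.approx(expected, abs=0.05)

    def test_seed_determinism(self):
        spec = VARSpec(order=2, coeffs=np.full((2, 2, 2), 0.1), noise_cov=np.eye(2))
        assert np.array_equal(simulate_var(spec, 500, seed=3),
                              simulate_var(spec, 500, seed=3))

    def test_short_series_rejected(self):
        spec = VARSpec(order=2, coeffs=np.zeros((2, 2, 2)), noise_cov=np.eye(2))
        with pytest.raises(ValueError):
            simulate_var(spec, n=150, seed=0)


class TestPulseTrain:
    def test_beat_count_and_pressure_targets(self):
        x, peaks, _ = generate_pulse_train(
            60, 120, 80, fs=125, duration_s=120, jitter=0.0, seed=0,
            return_beats=True,
        )
        assert x.size == 15_000
        assert 119 <= peaks.size <= 121
        assert 118 <= np.mean(x[peaks]) <= 122
        # per-beat minima near diastolic target
        minima = [x[peaks[i]:peaks[i + 1]].min() for i in range(peaks.size - 1)]
        assert 78 <= np.mean(minima) <= 82

    def test_zero_jitter_is_exactly_periodic(self):
        _, peaks, _ = generate_pulse_train(
            75, 130, 85, fs=125, duration_s=30, jitter=0.0, seed=1,
            return_beats=True,
        )
        assert np.unique(np.diff(peaks)).size == 1

    def test_hypertensive_construction_target(self):
        x, peaks, _ = generate_pulse_train(
            80, 150, 95, fs=125, duration_s=60, jitter=0.0, seed=2,
            return_beats=True,
        )
        assert 148 <= np.mean(x[peaks]) <= 152

    def test_guards(self):
        with pytest.raises(ValueError):
            generate_pulse_train(20, 120, 80)
        with pytest.raises(ValueError):
            generate_pulse_train(60, 80, 120)
        with pytest.raises(ValueError, match="duration"):
            generate_pulse_train(60, 120, 80, duration_s=0.5)


class TestDerivePPG:
    def test_identity_transfer(self):
        abp = generate_pulse_train(70, 120, 80, duration_s=30, seed=4)
        y = derive_ppg_from_abp(abp, 125, delay_ms=0, smooth_cutoff_hz=55,
                                gain=1.0, noise_sd=0.0)
        assert pearson_r(abp, y) > 0.999
        assert abs(y.mean()) < 1e-9

    def test_delay_shows_up_in_cross_correlation(self):
        abp = generate_pulse_train(70, 120, 80, duration_s=30, jitter=0.03, seed=5)
        y = derive_ppg_from_abp(abp, 125, delay_ms=200, smooth_cutoff_hz=55)
        a = abp - abp.mean()
        lags = np.arange(0, 60)
        xc = [np.dot(a[: a.size - k], y[k:]) for k in lags]
        assert lags[int(np.argmax(xc))] == 25  # 200 ms at 125 Hz

    def test_correlation_decreases_monotonically_with_noise(self):
        abp = generate_pulse_train(70, 120, 80, duration_s=60, jitter=0.02, seed=6)
        sd = np.std(abp)
        levels = [0.0, 1.0 * sd, 4.0 * sd]
        rs = []
        for i, noise in enumerate(levels):
            r_vals = [
                pearson_r(abp, derive_ppg_from_abp(
                    abp, 125, delay_ms=0, smooth_cutoff_hz=20,
                    noise_sd=noise, seed=100 + 7 * i + rep))
                for rep in range(5)
            ]
            rs.append(np.mean(r_vals))
        assert rs[0] > rs[1] > rs[2]

    def test_cutoff_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            derive_ppg_from_abp(np.zeros(100), 125, smooth_cutoff_hz=70)


class TestCohort:
    def test_study_size_and_determinism(self):
        spec = CohortSpec(n_per_group=(43, 40, 37), duration_s=10.0, seed=21)
        records = generate_cohort(spec)
        assert len(records) == 120
        assert sum(r.truth["group"] == "NT" for r in records) == 43
        again = generate_cohort(spec)
        for a, b in zip(records, again):
            assert np.array_equal(a.abp, b.abp) and np.array_equal(a.ppg, b.ppg)
            assert a.gain_subgroup == b.gain_subgroup

    def test_single_record_cohort(self):
        spec = CohortSpec(n_per_group=(1, 0, 0), duration_s=20.0, seed=2)
        (rec,) = generate_cohort(spec)
        assert rec.truth["group"] == "NT"
        assert rec.n_samples == int(20.0 * 125)
        assert 20.0 <= rec.abp.min() and rec.abp.max() <= 300.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="AHA band"):
            CohortSpec(sbp_range_mmHg=((95, 125), (122, 137), (142, 175)))
        with pytest.raises(ValueError, match="decrease"):
            CohortSpec(transit_delay_ms=(150, 200, 250))

    def test_sbp_labels_match_truth_on_200_records(self):
        """Measured SBP lands in the intended AHA band for >= 95% of records."""
        spec = CohortSpec(n_per_group=(67, 67, 66), duration_s=30.0, seed=8)
        records = generate_cohort(spec)
        hits = sum(classify_by_sbp(r) == r.truth["group"] for r in records)
        assert hits / len(records) >= 0.95

    def test_record_invariants(self):
        with pytest.raises(ValueError, match="equal length"):
            WaveformRecord("x", 125, np.zeros(10), np.zeros(9))
        with pytest.raises(ValueError, match="physiologic"):
            WaveformRecord("x", 125, np.full(10, 500.0), np.zeros(10),
                           truth={"group": "HT"})


def test_companion_matrix_shape_and_eigenstructure():
    coeffs = np.array([[[0.5, 0.1], [0.0, 0.3]], [[0.1, 0.0], [0.2, 0.1]]])
    comp = companion_matrix(coeffs)
    assert comp.shape == (4, 4)
    assert np.allclose(comp[2:, :2], np.eye(2))
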