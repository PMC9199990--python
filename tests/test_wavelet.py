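"""Combined-Morlet bank, phase extraction and the WPLI estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnet.simulate import CouplingSpec, simulate_recording
from somnet.wavelet import (BANDS, BandSpec, build_wavelet_bank,
                            connectivity_from_phase, epoch_connectivity,
                            extract_phase, wpli)


class TestWaveletBank:
    def test_delta_band_has_70_centers_from_half_hz(self):
        c = BANDS["delta"].centers
        assert len(c) == 70
        assert c[0] == 0.5
        assert np.allclose(np.diff(c), 0.05)
        assert np.isclose(c[-1], 3.95)

    def test_theta_band_has_80_centers_from_4hz(self):
        c = BANDS["theta"].centers
        assert len(c) == 80 and c[0] == 4.0 and np.isclose(c[-1], 7.95)

    def test_upper_bands_follow_the_same_pattern(self):
        assert len(BANDS["alpha"].centers) == 80
        assert len(BANDS["sigma"].centers) == 80
        assert len(BANDS["beta"].centers) == 320
        for b in ("alpha", "sigma", "beta"):
            spec = BANDS[b]
            assert spec.centers[0] == spec.f_low
            assert spec.centers[-1] <= spec.f_high

    def test_centers_outside_band_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            BandSpec("theta", 4.0, 8.0, 4.0, 200)

    @pytest.mark.parametrize("band", ["delta", "theta", "alpha"])
    def test_peak_response_is_unity_after_correction(self, band):
        bank = build_wavelet_bank(band, 200.0)
        spec = bank.band
        grid = np.arange(spec.f_low, spec.f_high, spec.df / 10)
        assert abs(bank.frequency_response(grid).max() - 1.0) < 1e-6

    def test_in_band_ripple_is_bounded(self):
        # away from the band edges the combined response is nearly flat;
        # with fb = 2 s^2 the interior ripple stays within 2% of peak
        bank = build_wavelet_bank("alpha", 200.0)
        interior = np.arange(8.5, 11.5, 0.01)
        resp = bank.frequency_response(interior)
        assert resp.min() > 0.98

    def test_low_sampling_rate_names_band(self):
        with pytest.raises(ValueError, match="beta"):
            build_wavelet_bank("beta", 60.0)


class TestPhaseExtraction:
    def test_two_hz_cosine_phase_slope(self):
        fs = 250.0
        bank = build_wavelet_bank("delta", fs)
        t = np.arange(int(60 * fs)) / fs
        ps = extract_phase(np.cos(2 * np.pi * 2.0 * t), bank)
        ph = np.unwrap(ps.phase[0][ps.valid])
        slope = np.polyfit(np.arange(ph.size) / fs, ph, 1)[0]
        assert abs(slope / (2 * np.pi * 2.0) - 1) < 0.01

    def test_quarter_period_shift_gives_half_pi_lag(self):
        fs = 250.0
        bank = build_wavelet_bank("delta", fs)
        t = np.arange(int(60 * fs)) / fs
        sig = np.vstack([np.cos(2 * np.pi * 2.0 * t),
                         np.cos(2 * np.pi * 2.0 * (t - 0.125))])
        ps = extract_phase(sig, bank)
        dphi = np.angle(np.exp(1j * (ps.phase[0] - ps.phase[1])))[ps.valid]
        assert np.max(np.abs(dphi - np.pi / 2)) < 0.01

    def test_zero_signal_zero_amplitude(self):
        bank = build_wavelet_bank("alpha", 100.0)
        ps = extract_phase(np.zeros(2000), bank)
        assert np.all(ps.amplitude == 0)

    def test_signal_shorter_than_kernel_rejected(self):
        bank = build_wavelet_bank("alpha", 100.0)
        with pytest.raises(ValueError, match="longer than"):
            extract_phase(np.zeros(100), bank)

    def test_edge_samples_flagged_invalid(self):
        bank = build_wavelet_bank("alpha", 100.0)
        ps = extract_phase(np.zeros(2000), bank)
        assert not ps.valid[0] and not ps.valid[-1]
        assert ps.valid[1000]
        assert ps.valid.sum() == 2000 - 2 * bank.half_len


class TestWpli:
    def test_constant_quarter_pi_lag_scores_one(self):
        a = np.full(100, 1.0)
        assert wpli(a + np.pi / 2, a) == 1.0

    def test_zero_lag_scores_zero_by_convention(self):
        a = np.linspace(-3, 3, 100)
        assert wpli(a, a) == 0.0

    def test_three_sample_worked_case_is_one_third(self):
        dphi = np.array([np.pi / 2, np.pi / 2, -np.pi / 2])
        assert np.isclose(wpli(dphi, np.zeros(3)), 1.0 / 3.0)

    def test_requires_two_valid_samples(self):
        with pytest.raises(ValueError, match="valid samples"):
            wpli([0.1], [0.0])

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_common_phase_invariance_and_range(self, seed):
        r = np.random.default_rng(seed)
        a = r.uniform(-np.pi, np.pi, 64)
        b = r.uniform(-np.pi, np.pi, 64)
        common = r.uniform(-np.pi, np.pi, 64)
        v = wpli(a, b)
        assert 0.0 <= v <= 1.0
        assert np.isclose(wpli(a + common, b + common), v)

    def test_one_iff_constant_sign(self, rng):
        d = rng.uniform(0.1, np.pi - 0.1, 50)  # sin(d) > 0 throughout
        assert np.isclose(wpli(d, np.zeros(50)), 1.0)
        d[0] = -0.5
        assert wpli(d, np.zeros(50)) < 1.0


class TestEpochConnectivity:
    def test_near_deterministic_lag_pair(self):
        spec = CouplingSpec(band="alpha", mu=[0.0, np.pi / 2],
                            kappa=[np.inf, 1000.0])
        rec = simulate_recording([spec], 30.0, 100.0, seed=1, noise_sd=0.0,
                                 channels=["C3", "C4"])
        mat = epoch_connectivity(rec.data, build_wavelet_bank("alpha", 100.0))
        assert mat[0, 1] >= 0.99

    def test_matrix_symmetric_zero_diagonal(self, rng):
        phase = rng.uniform(-np.pi, np.pi, size=(4, 600))
        mat = connectivity_from_phase(phase, np.ones(600, bool), 100.0)
        assert np.allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 0)
        assert np.all((mat >= 0) & (mat <= 1))

    def test_uncoupled_pair_shrinks_with_window_count(self):
        # Pooled over B independent 3-s coherence blocks the null WPLI is
        # approximately |N(0, pi^2/(8B))|, so its 95th percentile is
        # ~1.96*pi/sqrt(8B): about 0.35 for a 120-s segment (B = 40).
        bank = build_wavelet_bank("alpha", 100.0)
        spec = CouplingSpec(band="alpha", mu=[0.0, 0.0], kappa=[np.inf, 0.0])
        vals = []
        for seed in range(40):
            rec = simulate_recording([spec], 120.0, 100.0, seed=seed,
                                     noise_sd=0.0, channels=["C3", "C4"])
            ps = extract_phase(rec.data, bank)
            vals.append(connectivity_from_phase(ps.phase, ps.valid, 100.0)[0, 1])
        assert np.mean(np.asarray(vals) <= 0.35) >= 0.85  # binomial slack on 40 reps
        long = simulate_recording([spec], 1200.0, 100.0, seed=99,
                                  noise_sd=0.0, channels=["C3", "C4"])
        ps = extract_phase(long.data, bank)
        assert connectivity_from_phase(ps.phase, ps.valid, 100.0)[0, 1] < 0.12

    def test_window_mean_mode_runs_and_differs(self, rng):
        phase = rng.uniform(-np.pi, np.pi, size=(3, 1000))
        valid = np.ones(1000, bool)
        pooled = connectivity_from_phase(phase, valid, 100.0, aggregation="pooled")
        winm = connectivity_from_phase(phase, valid, 100.0,
                                       aggregation="window-mean")
        assert pooled.shape == winm.shape
        assert np.all((winm >= 0) & (winm <= 1))
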