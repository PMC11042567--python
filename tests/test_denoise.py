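import numpy as np
import pytest

from fnirsdep.denoise import (CeemdanConfig, WptConfig, benchmark_denoisers,
                              ceemdan_decompose, ceemdan_wpt_denoise,
                              emd_decompose, rmse, snr, split_high_low,
                              wpt_denoise_imf, zero_crossing_rate)
from fnirsdep.simulate import CohortSpec, simulate_cohort


def _two_tone(n=1200, fs=10.0):
    t = np.arange(n) / fs
    slow = np.sin(2 * np.pi * 0.05 * t)
    fast = 0.5 * np.sin(2 * np.pi * 1.0 * t)
    return slow, fast, slow + fast


class TestEmd:
    def test_monotonic_input_has_no_imfs(self):
        x = np.linspace(0, 5, 100)
        res = emd_decompose(x)
        assert res.n_imfs == 0
        np.testing.assert_array_equal(res.residual, x)

    def test_first_imf_captures_fast_tone(self):
        slow, fast, x = _two_tone()
        res = emd_decompose(x)
        assert res.n_imfs >= 2
        r = np.corrcoef(res.imfs[0], fast)[0, 1]
        assert r > 0.9

    def test_reconstruction_complete(self, rng):
        x = rng.standard_normal(600)
        res = emd_decompose(x)
        err = np.max(np.abs(res.reconstruct() - x))
        assert err <= 1e-8 * np.sqrt(np.mean(x**2))

    def test_rejects_short_or_nonfinite(self):
        with pytest.raises(ValueError):
            emd_decompose(np.arange(4.0))
        with pytest.raises(ValueError):
            emd_decompose(np.array([np.nan] * 100))


class TestCeemdan:
    CFG = CeemdanConfig(ensemble_size=20, seed=5)

    def test_zero_signal_exact(self):
        res = ceemdan_decompose(np.zeros(100), self.CFG)
        assert res.n_imfs == 0
        np.testing.assert_array_equal(res.residual, 0.0)

    def test_seeded_determinism(self, rng):
        x = rng.standard_normal(400)
        a = ceemdan_decompose(x, self.CFG)
        b = ceemdan_decompose(x, self.CFG)
        assert a.n_imfs == b.n_imfs
        for u, v in zip(a.imfs, b.imfs):
            np.testing.assert_array_equal(u, v)

    def test_reconstruction_complete(self, rng):
        x = rng.standard_normal(400) + np.linspace(0, 3, 400)
        res = ceemdan_decompose(x, self.CFG)
        err = np.max(np.abs(res.reconstruct() - x))
        assert err <= 1e-8 * np.sqrt(np.mean(x**2))

    def test_mode_separation_at_least_plain_emd(self):
        """Noise-assisted averaging resists the mode mixing that an
        intermittent high-frequency burst induces in plain EMD."""
        slow, fast, x = _two_tone()
        t = np.arange(x.size) / 10.0
        burst = np.zeros_like(x)
        m = (t > 40) & (t < 50)
        burst[m] = 0.3 * np.sin(2 * np.pi * 3.0 * t[m])
        x = x + burst
        cfg = CeemdanConfig(ensemble_size=50, seed=2)

        def mixing_score(imfset):
            best_fast = max(
                abs(np.corrcoef(imf, fast)[0, 1]) for imf in imfset.imfs
            )
            best_slow = max(
                abs(np.corrcoef(c, slow)[0, 1])
                for c in imfset.imfs + [imfset.residual]
                if np.std(c) > 0
            )
            return best_fast + best_slow

        assert mixing_score(ceemdan_decompose(x, cfg)) >= \
            mixing_score(emd_decompose(x)) - 0.02

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CeemdanConfig(ensemble_size=1)
        with pytest.raises(ValueError):
            ceemdan_decompose(np.full(100, np.inf), self.CFG)


class TestWpt:
    def test_zero_in_zero_out(self):
        out = wpt_denoise_imf(np.zeros(256))
        np.testing.assert_array_equal(out, 0.0)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(7)
        w = rng.standard_normal(1200)
        out = wpt_denoise_imf(w)
        assert out.var() < 0.2 * w.var()

    def test_smooth_signal_preserved(self):
        t = np.linspace(0, 1, 600)
        p = 1 + 2 * t - 3 * t**2
        out = wpt_denoise_imf(p)
        rel = np.sqrt(np.mean((out - p) ** 2) / np.mean(p**2))
        assert rel < 0.05

    def test_level_too_deep_rejected(self):
        with pytest.raises(ValueError):
            wpt_denoise_imf(np.zeros(4), WptConfig(decomposition_level=11))


class TestCeemdanWpt:
    def test_clean_smooth_signal_roundtrip(self):
        t = np.arange(1200) / 10.0
        x = np.sin(2 * np.pi * 0.05 * t)
        out, _ = ceemdan_wpt_denoise(
            x, CeemdanConfig(ensemble_size=20, seed=1), sampling_hz=10.0
        )
        rel = np.sqrt(np.mean((out - x) ** 2) / np.mean(x**2))
        assert rel < 0.05

    def test_snr_improves_on_noisy_mixture(self, inband_noise_profile):
        spec = CohortSpec(n_severe=1, n_mild=0, n_channels=2,
                          noise_profile=inband_noise_profile, seed=13)
        subj = simulate_cohort(spec)[0]
        noisy = subj.recording.data[:, 0, 0]
        clean = subj.ground_truth[:, 0, 0]
        out, _ = ceemdan_wpt_denoise(
            noisy, CeemdanConfig(ensemble_size=30, seed=0),
            sampling_hz=10.0,
        )
        assert snr(clean, out) > snr(clean, noisy)

    def test_high_and_low_groups_both_nonempty(self, inband_noise_profile):
        spec = CohortSpec(n_severe=1, n_mild=0, n_channels=2,
                          noise_profile=inband_noise_profile, seed=13)
        subj = simulate_cohort(spec)[0]
        imfset = ceemdan_decompose(subj.recording.data[:, 0, 0],
                                   CeemdanConfig(ensemble_size=30, seed=0))
        high, low = split_high_low(imfset, 10.0)
        assert high and low


class TestMetrics:
    def test_snr_half_signal(self, rng):
        x = rng.standard_normal(100)
        assert snr(x, 0.5 * x) == pytest.approx(10 * np.log10(4.0))

    def test_snr_zero_estimate(self, rng):
        x = rng.standard_normal(100)
        assert snr(x, np.zeros_like(x)) == pytest.approx(0.0)

    def test_snr_exact_match_is_inf(self, rng):
        x = rng.standard_normal(10)
        assert snr(x, x.copy()) == np.inf

    def test_snr_zero_energy_rejected(self):
        with pytest.raises(ValueError):
            snr(np.zeros(5), np.ones(5))

    def test_rmse_hand_value(self):
        assert rmse(np.array([0.0, 0.0]),
                    np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))

    def test_rmse_identity_and_symmetry(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        assert rmse(x, x) == 0.0
        assert rmse(x, y) == pytest.approx(rmse(y, x))

    def test_metrics_match_closed_form_on_random_vectors(self, rng):
        x, y = rng.standard_normal(64), rng.standard_normal(64)
        expect_snr = 10 * np.log10(np.sum(x**2) / np.sum((x - y) ** 2))
        expect_rmse = np.sqrt(np.sum((x - y) ** 2) / 64)
        assert snr(x, y) == pytest.approx(expect_snr, abs=1e-12)
        assert rmse(x, y) == pytest.approx(expect_rmse, abs=1e-12)


def test_zero_crossing_rate_matches_tone_frequency():
    t = np.arange(1200) / 10.0
    for f in (0.3, 1.0):
        x = np.sin(2 * np.pi * f * t)
        assert zero_crossing_rate(x, 10.0) == pytest.approx(f, rel=0.05)


class TestBenchmark:
    def test_noise_free_fixture_rmse_near_zero(self):
        from fnirsdep.simulate import NoiseProfile
        prof = NoiseProfile(0, 0, 0, 0, 0, 0, 0)
        spec = CohortSpec(n_severe=1, n_mild=0, n_channels=2,
                          noise_profile=prof, seed=4)
        reports = benchmark_denoisers(
            simulate_cohort(spec),
            ceemdan=CeemdanConfig(ensemble_size=10, seed=0),
        )
        for rep in reports:
            assert rep.rmse < 0.05

    def test_empty_fixture_set_rejected(self):
        with pytest.raises(ValueError):
            benchmark_denoisers([])
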