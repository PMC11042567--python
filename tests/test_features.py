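import numpy as np
import pytest

from fnirsdep.features import (TF_KINDS, build_feature_table,
                               correlation_features,
                               mean_square_frequency,
                               power_spectral_entropy,
                               singular_spectral_entropy,
                               temporal_features)
from fnirsdep.io import HemoRecording
from fnirsdep.simulate import TaskParadigm


def _sine(n=600, fs=10.0, f=0.5, amp=1.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * f * t)


class TestTemporalFeatures:
    def test_sine_closed_forms(self):
        x = _sine(f=0.5)  # 30 cycles in 60 s, bin-aligned
        tf = temporal_features(x)
        assert tf.peak_factor == pytest.approx(np.sqrt(2), rel=1e-3)
        assert tf.skewness == pytest.approx(0.0, abs=1e-6)
        assert tf.max == pytest.approx(1.0, rel=1e-3)
        assert tf.rect_mean >= abs(tf.mean)

    def test_bin_aligned_tone_entropy_and_msf(self):
        f0 = 0.5
        x = _sine(f=f0)
        assert power_spectral_entropy(x) == pytest.approx(0.0, abs=1e-8)
        assert mean_square_frequency(x) == pytest.approx(f0**2, rel=1e-9)

    def test_impulse_has_flat_spectrum_entropy(self):
        """A unit impulse has an exactly flat periodogram: H_f = ln(bins)."""
        x = np.zeros(600)
        x[0] = 1.0
        n_bins = 301  # one-sided bins for n=600
        assert power_spectral_entropy(x) == pytest.approx(np.log(n_bins),
                                                          rel=1e-12)

    def test_white_noise_entropy_near_theoretical_mean(self):
        """Periodogram bins of white noise are exponentially distributed,
        so E[H_f] ≈ ln(bins) − (1 − γ) with γ Euler's constant."""
        vals = []
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(600)
            vals.append(power_spectral_entropy(x))
        expect = np.log(301) - (1 - np.euler_gamma)
        assert np.mean(vals) == pytest.approx(expect, rel=0.02)

    def test_constant_signal_sentinels(self):
        tf = temporal_features(np.full(100, 3.0))
        assert tf.skewness == 0.0
        assert tf.peak_factor == 1.0


class TestSingularSpectralEntropy:
    def test_constant_signal_rank_one(self):
        assert singular_spectral_entropy(np.full(200, 2.0), 50) == \
            pytest.approx(0.0, abs=1e-10)

    def test_sine_two_equal_singular_values(self):
        x = _sine(n=600, f=0.5)
        assert singular_spectral_entropy(x, 50) == pytest.approx(np.log(2),
                                                                 abs=0.01)

    def test_matches_bruteforce_svd(self, rng):
        x = rng.standard_normal(120)
        m = 20
        # independent brute-force construction
        traj = np.array([x[i:i + 120 - m + 1] for i in range(m)])
        sv = np.linalg.svd(traj, compute_uv=False)
        p = sv / sv.sum()
        expect = -np.sum(p * np.log(p))
        assert singular_spectral_entropy(x, m) == pytest.approx(expect,
                                                                abs=1e-10)

    def test_embed_len_bounds(self):
        with pytest.raises(ValueError):
            singular_spectral_entropy(np.arange(10.0), 1)
        with pytest.raises(ValueError):
            singular_spectral_entropy(np.arange(10.0), 10)


class TestPowerSpectralEntropy:
    def test_matches_bruteforce_summation(self, rng):
        x = rng.standard_normal(256)
        spec = np.abs(np.fft.rfft(x)) ** 2
        p = spec / spec.sum()
        expect = -sum(pi * np.log(pi) for pi in p if pi > 0)
        assert power_spectral_entropy(x) == pytest.approx(expect, abs=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            power_spectral_entropy(np.zeros(100))


def _recording(data, paradigm=None):
    return HemoRecording(data=data, sampling_hz=10.0,
                         paradigm=paradigm or TaskParadigm())


class TestCorrelationFeatures:
    def test_identical_channels_r_one(self, rng):
        base = rng.standard_normal(1200)
        data = np.stack([np.stack([base, base], axis=1)] * 2, axis=2)
        rec = _recording(data)
        cf = correlation_features(rec)
        np.testing.assert_allclose(cf, 1.0, atol=1e-12)

    def test_negated_channel_r_minus_one(self, rng):
        base = rng.standard_normal(1200)
        data = np.stack([np.stack([base, -base], axis=1)] * 2, axis=2)
        cf = correlation_features(_recording(data))
        np.testing.assert_allclose(cf, -1.0, atol=1e-12)

    def test_hand_computed_pearson(self):
        # r([1,2,3],[1,2,4]) computed by the raw product-moment formula
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        n = 3
        num = np.sum(x * y) - np.sum(x) * np.sum(y) / n
        den = np.sqrt((np.sum(x**2) - np.sum(x) ** 2 / n)
                      * (np.sum(y**2) - np.sum(y) ** 2 / n))
        expect = num / den
        assert expect == pytest.approx(0.98198, abs=1e-4)
        paradigm = TaskParadigm(pre_rest_s=0.1, task_s=0.3, post_rest_s=0.1,
                                sampling_hz=10.0)
        data = np.zeros((5, 2, 2))
        data[1:4, 0, :] = x[:, None]
        data[1:4, 1, :] = y[:, None]
        cf = correlation_features(_recording(data, paradigm))
        np.testing.assert_allclose(cf, expect, atol=1e-9)

    def test_zero_variance_channel_yields_zero(self, rng):
        data = rng.standard_normal((1200, 3, 2))
        data[:, 1, 0] = 5.0  # constant channel
        cf = correlation_features(_recording(data))
        # pairs (0,1) and (1,2) for HbO are the first and third entries
        assert cf[0] == 0.0 and cf[2] == 0.0


class TestFeatureTable:
    def _cohort_tables(self, small_cohort, families):
        recs = [s.recording for s in small_cohort]
        labels = [s.label for s in small_cohort]
        return build_feature_table(recs, labels, families=families)

    @pytest.mark.parametrize("families,expected", [
        (("TF",), 4 * 2 * 9),
        (("CF",), 6 * 2),
        (("TF", "CF"), 72 + 12),
    ])
    def test_column_count_formula(self, small_cohort, families, expected):
        table = self._cohort_tables(small_cohort, families)
        assert table.n_features == expected

    def test_column_names_deterministic_and_tagged(self, small_cohort):
        table = self._cohort_tables(small_cohort, ("TF", "CF"))
        names = table.feature_names
        assert names[0] == "TF.max.ch01.HbO"
        assert any(n.startswith("CF.pearson.ch01-ch02.") for n in names)
        assert len(set(names)) == len(names)

    def test_scale_covariance(self, small_cohort):
        """Scaling a recording by c>0 leaves shape features (skewness,
        peak factor, entropies, correlations) unchanged and scales the
        amplitude features by c."""
        rec = small_cohort[0].recording
        scaled = rec.copy_with(rec.data * 3.0)
        t1 = build_feature_table([rec], ["mild"], families=("TF", "CF"))
        t2 = build_feature_table([scaled], ["mild"], families=("TF", "CF"))
        for name in t1.feature_names:
            v1 = t1.values[name].iloc[0]
            v2 = t2.values[name].iloc[0]
            kind = name.split(".")[1]
            if kind in ("max", "min", "mean", "rect_mean"):
                assert v2 == pytest.approx(3.0 * v1, rel=1e-9)
            elif kind == "mean_square_freq":
                assert v2 == pytest.approx(v1, rel=1e-9)
            else:  # skewness, peak factor, entropies, pearson
                assert v2 == pytest.approx(v1, abs=1e-9)

    def test_heterogeneous_channels_rejected(self, small_cohort, rng):
        recs = [s.recording for s in small_cohort[:2]]
        odd = HemoRecording(data=rng.standard_normal((1200, 7, 2)),
                            sampling_hz=10.0, paradigm=TaskParadigm())
        with pytest.raises(ValueError, match="channel"):
            build_feature_table(recs + [odd], ["mild"] * 3)
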