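"""Feature mathematics: closed forms, brute-force oracles, invariances."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ehgkit.features import (
    FEATURE_NAMES,
    FeatureConfig,
    UndefinedFeature,
    dominant_frequency,
    extract_features,
    fuzzy_entropy,
    hl_energy_ratio,
    lempel_ziv,
    peak_to_peak,
    poincare_descriptors,
    power_spectrum,
    sample_entropy,
    spectral_deciles,
    spectral_entropy,
    teager_energy,
    time_reversibility,
    window_features,
)
from ehgkit._fast import fuzzen_phis, lz76_complexity, sampen_counts
from ehgkit.recording import EHGRecording

from oracles import fuzzen_bruteforce, lz76_bruteforce, sampen_bruteforce


class TestTemporal:
    def test_peak_to_peak_values(self):
        assert peak_to_peak(np.zeros(10)) == 0.0
        assert peak_to_peak(np.array([-3.0, 1.0, 4.0])) == 7.0
        t = np.arange(2400) / 20.0
        assert abs(peak_to_peak(np.sin(2 * np.pi * 0.5 * t)) - 2.0) < 0.02

    def test_teager_constant_zero(self):
        assert teager_energy(np.full(100, 3.3)) == 0.0

    def test_teager_tone_closed_form(self):
        # psi of A sin(w n) is A^2 sin^2(w)
        for amp, f in [(1.0, 0.5), (3.0, 1.0)]:
            w = 2 * np.pi * f / 20.0
            x = amp * np.sin(w * np.arange(2400))
            expect = amp**2 * np.sin(w) ** 2
            assert abs(teager_energy(x) - expect) / expect < 0.01

    def test_teager_quadratic_scaling(self):
        x = np.random.default_rng(3).standard_normal(500)
        assert teager_energy(2 * x) == pytest.approx(4 * teager_energy(x))


class TestPowerSpectrum:
    def test_parseval(self, rng):
        x = rng.standard_normal(2400)
        f, p = power_spectrum(x, 20.0)
        assert abs(np.trapezoid(p, f) - np.var(x)) / np.var(x) < 0.01

    def test_tone_peak_location(self):
        t = np.arange(2400) / 20.0
        f, p = power_spectrum(np.sin(2 * np.pi * 0.5 * t), 20.0)
        assert abs(f[np.argmax(p)] - 0.5) < 0.04

    def test_white_noise_flat(self, rng):
        """log-PSD slope over frequency not significantly nonzero (100 runs)."""
        slopes = []
        for _ in range(100):
            f, p = power_spectrum(rng.standard_normal(2400), 20.0)
            sel = (f > 0.5) & (f < 9.5)
            slopes.append(np.polyfit(f[sel], np.log(p[sel]), 1)[0])
        slopes = np.asarray(slopes)
        assert abs(slopes.mean()) < 3 * slopes.std(ddof=1) / math.sqrt(len(slopes))


class TestSpectralFeatures:
    def setup_method(self):
        self.f = np.linspace(0.0, 10.0, 2001)  # 5 mHz grid

    def _tone_psd(self, freqs):
        p = np.zeros_like(self.f)
        for f0, a in freqs:
            p[np.argmin(np.abs(self.f - f0))] = a
        return p

    def test_dominant_frequency_tone(self):
        p = self._tone_psd([(0.5, 1.0)])
        assert dominant_frequency(self.f, p, (0.34, 1.0)) == pytest.approx(0.5)
        assert dominant_frequency(self.f, p, (0.2, 1.0)) == pytest.approx(0.5)

    def test_dominant_frequency_band_matters(self):
        p = self._tone_psd([(0.25, 1.0)])
        assert dominant_frequency(self.f, p, (0.2, 1.0)) == pytest.approx(0.25)
        with pytest.raises(UndefinedFeature):
            dominant_frequency(self.f, p, (0.34, 1.0))  # no energy in band

    def test_flat_psd_tie_breaks_low(self):
        p = np.ones_like(self.f)
        assert dominant_frequency(self.f, p, (0.34, 1.0)) == pytest.approx(0.34, abs=0.01)

    def test_hl_ratio_balanced_tones(self):
        p = self._tone_psd([(0.25, 1.0), (0.5, 1.0)])
        assert hl_energy_ratio(self.f, p) == pytest.approx(1.0, rel=0.05)

    def test_hl_ratio_extremes(self):
        low_only = self._tone_psd([(0.25, 1.0), (0.5, 1e-9)])
        assert hl_energy_ratio(self.f, low_only) < 0.01
        high_only = self._tone_psd([(0.25, 1e-9), (0.5, 1.0)])
        assert hl_energy_ratio(self.f, high_only) > 100

    def test_flat_psd_deciles_uniform(self):
        f = np.arange(0.2, 1.0 + 1e-9, 1e-4)
        d = spectral_deciles(f, np.ones_like(f), (0.2, 1.0))
        np.testing.assert_allclose(d, 0.2 + 0.08 * np.arange(1, 10), atol=2e-4)

    def test_point_mass_deciles(self):
        p = self._tone_psd([(0.5, 1.0)])
        np.testing.assert_allclose(spectral_deciles(self.f, p), 0.5, atol=1e-6)

    def test_deciles_match_cumsum_oracle(self, rng):
        f = np.linspace(0.2, 1.0, 400)
        p = rng.uniform(0.1, 1.0, size=400)
        d = spectral_deciles(f, p, (0.2, 1.0))
        cum = np.cumsum(p) / p.sum()
        for k in range(1, 10):
            expect = f[np.flatnonzero(cum >= k / 10.0 - 1e-12)[0]]
            assert d[k - 1] == pytest.approx(expect)
        assert np.all(np.diff(d) >= 0)

    def test_spectral_entropy_extremes(self):
        f = np.linspace(0.34, 4.0, 500)
        assert spectral_entropy(f, np.ones_like(f), (0.34, 4.0)) == pytest.approx(1.0)
        point = np.zeros(500)
        point[200] = 5.0
        assert spectral_entropy(f, point, (0.34, 4.0)) == 0.0

    def test_spectral_entropy_direct_formula(self, rng):
        f = np.linspace(0.34, 4.0, 200)
        p = rng.uniform(0.01, 1.0, 200)
        prob = p / p.sum()
        expect = -np.sum(prob * np.log(prob)) / np.log(len(prob))
        assert spectral_entropy(f, p, (0.34, 4.0)) == pytest.approx(expect, rel=1e-12)


class TestEntropyOracles:
    """Compiled kernels against naive brute-force implementations."""

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("kind", ["noise", "tonal"])
    def test_sample_and_fuzzy_entropy_bruteforce(self, seed, kind):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(80, 200))
        if kind == "noise":
            x = rng.standard_normal(n)
        else:
            x = np.sin(2 * np.pi * 0.4 * np.arange(n) / 20.0) + 0.3 * rng.standard_normal(n)
        r = 0.15 * x.std()
        assert sampen_counts(x, 2, r) == sampen_bruteforce(list(x), 2, r)
        got = fuzzy_entropy(x, 2, 0.15, 2.0)
        expect = fuzzen_bruteforce(list(x), 2, r, 2.0)
        assert abs(got - expect) <= 1e-9 * abs(expect)

    def test_sample_entropy_constant_window(self):
        assert sample_entropy(np.full(100, 2.0)) == 0.0
        assert fuzzy_entropy(np.full(100, 2.0)) == 0.0

    def test_entropy_orders_noise_above_periodic(self, rng):
        periodic, noisy = [], []
        for _ in range(10):
            n = 300
            periodic.append(
                sample_entropy(np.sin(2 * np.pi * 0.4 * np.arange(n) / 20.0)
                               + 0.05 * rng.standard_normal(n))
            )
            noisy.append(sample_entropy(rng.standard_normal(n)))
        assert np.mean(periodic) < np.mean(noisy)
        fuz_p = [fuzzy_entropy(np.sin(2 * np.pi * 0.4 * np.arange(300) / 20.0)
                               + 0.05 * rng.standard_normal(300)) for _ in range(5)]
        fuz_n = [fuzzy_entropy(rng.standard_normal(300)) for _ in range(5)]
        assert np.mean(fuz_p) < np.mean(fuz_n)

    def test_sample_entropy_no_matches_flagged(self):
        # strictly growing ramp with steps far beyond the tolerance
        x = np.arange(40, dtype=float)
        with pytest.raises(UndefinedFeature):
            sample_entropy(x, 2, 0.001)


class TestLempelZiv:
    def test_known_binary_parse(self):
        s = np.array([int(c) for c in "0001101001000101"])
        assert lz76_complexity(s) == 6

    @pytest.mark.parametrize("seed", range(10))
    def test_random_strings_match_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(10, 200))
        levels = int(rng.choice([2, 6]))
        s = rng.integers(0, levels, size=n)
        assert lz76_complexity(s) == lz76_bruteforce(list(s))

    def test_constant_window_minimal_complexity(self):
        n = 600
        assert lempel_ziv(np.full(n, 1.5), 2) == pytest.approx(math.log2(n) / n)

    def test_iid_multistate_normalization_approaches_one(self, rng):
        vals = []
        for _ in range(50):
            x = rng.uniform(size=2400)
            vals.append(lempel_ziv(x, 6))
        assert abs(np.mean(vals) - 1.0) < 0.10

    def test_quantization_level_count(self, rng):
        from ehgkit.features import _quantize

        x = rng.standard_normal(1200)
        q6 = _quantize(x, 6)
        counts = np.bincount(q6, minlength=6)
        assert q6.min() == 0 and q6.max() == 5
        assert counts.min() > 150  # near-equal occupancy

    def test_binary_median_split(self):
        q = __import__("ehgkit.features", fromlist=["_quantize"])._quantize(
            np.array([1.0, 2.0, 3.0, 4.0]), 2
        )
        np.testing.assert_array_equal(q, [0, 0, 1, 1])


class TestTimeReversibility:
    def test_alternating_signal_zero(self):
        # odd length -> an even number of lag-1 differences, cubes cancel
        x = np.append(np.tile([1.0, -1.0], 50), 1.0)
        assert time_reversibility(x, 1) == pytest.approx(0.0)

    def test_unit_ramp_one(self):
        assert time_reversibility(np.arange(100, dtype=float), 1) == pytest.approx(1.0)

    def test_gaussian_ar1_reversible(self, rng):
        """Linear Gaussian processes have zero third-order asymmetry."""
        vals = []
        for _ in range(100):
            e = rng.standard_normal(2000)
            x = np.empty(2000)
            x[0] = e[0]
            for i in range(1, 2000):
                x[i] = 0.8 * x[i - 1] + e[i]
            vals.append(time_reversibility(x, 1))
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / math.sqrt(len(vals))


class TestPoincare:
    def test_white_noise_circular_cloud(self, rng):
        x = 2.5 * rng.standard_normal(2400)
        sd1, sd2, ratio = poincare_descriptors(x)
        assert sd1 == pytest.approx(2.5, rel=0.05)
        assert sd2 == pytest.approx(2.5, rel=0.05)
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_slow_sinusoid_elongated(self):
        t = np.arange(2400) / 20.0
        _, _, ratio = poincare_descriptors(np.sin(2 * np.pi * 0.05 * t))
        assert ratio < 0.1

    def test_short_vector_direct_formula(self):
        x = np.array([0.0, 1.0, 2.0, 1.0])
        sd1, sd2, ratio = poincare_descriptors(x)
        expect_sd1 = math.sqrt(np.var(np.diff(x)) / 2)
        expect_sd2 = math.sqrt(2 * np.var(x) - np.var(np.diff(x)) / 2)
        assert sd1 == pytest.approx(expect_sd1)
        assert sd2 == pytest.approx(expect_sd2)
        assert ratio == pytest.approx(expect_sd1 / expect_sd2)

    def test_constant_window_undefined(self):
        with pytest.raises(UndefinedFeature):
            poincare_descriptors(np.full(10, 1.0))


@pytest.fixture(scope="module")
def gain_window():
    rng = np.random.default_rng(99)
    t = np.arange(2400) / 20.0
    return np.sin(2 * np.pi * 0.45 * t) + 0.5 * rng.standard_normal(2400)


class TestScaleBehavior:
    """Gain response of each feature class."""

    def test_scale_invariant_features(self, gain_window):
        window = gain_window
        cfg = FeatureConfig()
        a = window_features(window, 20.0, cfg)
        b = window_features(10.0 * window, 20.0, cfg)
        for name in ("lz_bin", "lz_multi", "sampen", "fuzzen", "specen", "sd_ratio",
                     "df1", "df2", "hl_ratio", "d5"):
            assert a[name] == pytest.approx(b[name], rel=1e-6), name

    def test_gain_powers(self, gain_window):
        window = gain_window
        cfg = FeatureConfig()
        a = window_features(window, 20.0, cfg)
        b = window_features(3.0 * window, 20.0, cfg)
        for name, power in [("app", 1), ("teager", 2), ("sd1", 1), ("sd2", 1), ("tr", 3)]:
            assert b[name] == pytest.approx(a[name] * 3.0**power, rel=1e-6), name


class TestExtractFeatures:
    def test_vector_has_23_named_features(self):
        rng = np.random.default_rng(0)
        rec = EHGRecording(rng.standard_normal(4800), fs=20.0, recording_id="r0")
        fv = extract_features(rec)
        assert list(fv.index) == list(FEATURE_NAMES)
        assert len(fv) == 23
        assert fv.notna().all()

    def test_single_window_passthrough(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2400)
        rec = EHGRecording(x, fs=20.0)
        fv = extract_features(rec)
        direct = window_features(x, 20.0, FeatureConfig())
        for name in FEATURE_NAMES:
            assert fv[name] == pytest.approx(direct[name], nan_ok=True)

    def test_median_is_window_permutation_invariant(self):
        vals = np.array([1.0, 5.0, 100.0])
        assert np.median(vals) == np.median(vals[::-1]) == 5.0

    def test_band_containment(self, small_cohort_features):
        f = small_cohort_features
        assert ((f["df1"] >= 0.2) & (f["df1"] <= 1.0)).all()
        assert ((f["df2"] >= 0.34) & (f["df2"] <= 1.0)).all()
        for k in range(1, 10):
            assert ((f[f"d{k}"] >= 0.2) & (f[f"d{k}"] <= 1.0)).all()
        deciles = f[[f"d{k}" for k in range(1, 10)]].to_numpy()
        assert (np.diff(deciles, axis=1) >= 0).all()
        assert ((f["specen"] >= 0) & (f["specen"] <= 1)).all()
        assert (f["sd1"] >= 0).all() and (f["sd2"] >= 0).all()

    def test_fully_masked_recording_rejected(self):
        rec = EHGRecording(np.zeros(4800), fs=20.0,
                           artifact_mask=np.ones(4800, dtype=bool))
        with pytest.raises(ValueError, match="no artifact-free window"):
            extract_features(rec)
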