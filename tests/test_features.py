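import numpy as np
import pytest

from vtapredict import features
from vtapredict.datatypes import FEATURE_NAMES, RRSeries
from vtapredict.features import (
    SpectralConfig,
    SpectralError,
    band_powers,
    band_powers_from_tachogram,
    extract_features,
    mean_nn,
    pnn50,
    poincare_sd,
    rmssd,
    rr_to_tachogram,
    sdnn,
)

from .oracles import mean_loop, pnn50_loop, rmssd_loop, sd1_loop, sdnn_loop


class TestTimeDomain:
    def test_mean_examples(self):
        assert mean_nn([800, 800, 800]) == 800
        assert mean_nn([600, 800]) == 700
        assert mean_nn([712, 845, 699, 804]) == 765.0

    def test_sdnn_examples(self):
        assert sdnn([700] * 10) == 0
        assert sdnn([600, 800]) == 100.0
        assert sdnn([700]) == 0  # population convention for a single interval

    def test_sdnn_sample_flag(self):
        assert sdnn([600, 800], population=False) == pytest.approx(np.sqrt(20000))

    def test_rmssd_examples(self):
        assert rmssd([700] * 5) == 0
        assert rmssd([600, 700, 800]) == 100.0
        assert rmssd([600, 800, 600]) == 200.0

    def test_pnn50_examples(self):
        assert pnn50([800, 800, 800]) == 0
        # 2 qualifying diffs over N=3 total intervals
        assert pnn50([600, 700, 800]) == pytest.approx(200 / 3)
        # strict inequality at exactly 50 ms
        assert pnn50([600, 650, 700, 750]) == 0

    def test_pnn50_diff_denominator_flag(self):
        assert pnn50([600, 700, 800], denominator="diffs") == 100.0

    @pytest.mark.parametrize("func", [mean_nn, sdnn])
    def test_empty_input_errors(self, func):
        with pytest.raises(ValueError):
            func([])

    @pytest.mark.parametrize("func", [rmssd, pnn50, poincare_sd])
    def test_single_interval_errors(self, func):
        with pytest.raises(ValueError):
            func([700])


class TestPoincare:
    def test_constant_series(self):
        sd1, sd2, ratio = poincare_sd([700] * 10)
        assert sd1 == 0 and sd2 == 0
        assert np.isnan(ratio)

    def test_alternating_series_sd1(self):
        sd1, _, _ = poincare_sd([600, 800, 600, 800, 600])
        assert sd1 == pytest.approx(np.sqrt(20000))

    def test_alternating_series_sd2_identity(self):
        # sdnn^2 = 9600 (mean 680), sd1^2 = 20000: sd2 = sqrt(2*9600 - 10000)
        x = [600, 800, 600, 800, 600]
        assert sdnn(x) ** 2 == pytest.approx(9600)
        _, sd2, _ = poincare_sd(x)
        assert sd2 == pytest.approx(np.sqrt(9200))

    def test_rmssd_sd1_relation_for_zero_mean_diffs(self):
        # odd-length alternating series: successive differences have zero
        # mean, where rmssd^2 = 2*sd1^2 (population variance convention)
        x = [600, 800] * 10 + [600]
        sd1, _, _ = poincare_sd(x)
        assert rmssd(x) ** 2 == pytest.approx(2 * sd1**2)


class TestOracleEquivalence:
    def test_brute_force_agreement_on_random_series(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 120))
            x = rng.uniform(300, 1500, n)
            lst = x.tolist()
            assert mean_nn(x) == pytest.approx(mean_loop(lst), rel=1e-9)
            assert sdnn(x) == pytest.approx(sdnn_loop(lst), rel=1e-9, abs=1e-9)
            assert rmssd(x) == pytest.approx(rmssd_loop(lst), rel=1e-9)
            assert pnn50(x) == pytest.approx(pnn50_loop(lst), rel=1e-9)
            assert poincare_sd(x)[0] == pytest.approx(sd1_loop(lst), rel=1e-9, abs=1e-9)

    def test_sd2_identity_holds_pre_clamp(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            x = rng.uniform(300, 1500, int(rng.integers(2, 120)))
            sd1, sd2, _ = poincare_sd(x)
            assert 2 * sdnn(x) ** 2 - 0.5 * sd1**2 - sd2**2 == pytest.approx(
                0.0, abs=1e-6
            )


class TestFrequencyDomain:
    def test_constant_tachogram_has_no_power(self):
        vlf, lf, hf, ratio = band_powers_from_tachogram(np.full(1024, 700.0))
        assert vlf == pytest.approx(0, abs=1e-12)
        assert lf == pytest.approx(0, abs=1e-12)
        assert hf == pytest.approx(0, abs=1e-12)
        assert np.isnan(ratio)

    def test_pure_lf_sinusoid_concentrates_in_lf_band(self):
        t = np.arange(1024) / 4.0
        x = 50 * np.sin(2 * np.pi * 0.1 * t)
        vlf, lf, hf, _ = band_powers_from_tachogram(x)
        assert lf / (vlf + lf + hf) >= 0.95

    def test_pure_hf_sinusoid_concentrates_in_hf_band(self):
        t = np.arange(1024) / 4.0
        x = 50 * np.sin(2 * np.pi * 0.25 * t)
        vlf, lf, hf, _ = band_powers_from_tachogram(x)
        assert hf / (vlf + lf + hf) >= 0.95

    def test_parseval_total_power_matches_variance(self, rng):
        from scipy.signal import welch

        x = rng.normal(0, 30, 2048)
        cfg = SpectralConfig()
        x0 = x - x.mean()
        freqs, psd = welch(
            x0, fs=cfg.resample_rate, window="hann", nperseg=256, noverlap=128,
            detrend=False,
        )
        total = psd.sum() * (freqs[1] - freqs[0])
        assert total == pytest.approx(x0.var(), rel=0.05)
        # and the in-band portion reported by band_powers is consistent
        vlf, lf, hf, _ = band_powers_from_tachogram(x, cfg)
        in_band = (freqs < 0.4)
        assert vlf + lf + hf == pytest.approx(psd[in_band].sum() * (freqs[1] - freqs[0]), rel=1e-9)

    def test_tachogram_resampling_even_grid(self):
        rr = np.full(500, 800.0)
        tach = rr_to_tachogram(rr, 4.0)
        assert np.allclose(tach, 800.0)
        assert tach.size == pytest.approx(500 * 0.8 * 4, abs=5)

    def test_too_short_signal_errors(self):
        with pytest.raises(SpectralError):
            band_powers_from_tachogram(np.zeros(100))

    def test_beat_series_lf_modulation_lands_in_lf_band(self):
        t = np.cumsum(np.full(600, 800.0)) / 1000.0
        rr = 800 + 60 * np.sin(2 * np.pi * 0.1 * t)
        vlf, lf, hf, ratio = band_powers(rr)
        assert lf > 10 * hf
        assert ratio > 10


class TestExtractFeatures:
    def test_vector_has_eleven_named_entries(self, rng):
        x = rng.uniform(600, 1000, 400)
        vec = extract_features(x)
        assert vec.as_array().shape == (11,)
        assert set(vec.as_dict()) == set(FEATURE_NAMES)

    def test_constant_series_degenerates(self):
        vec = extract_features(np.full(400, 700.0))
        assert vec.mean_nn == 700
        assert vec.sdnn == 0 and vec.rmssd == 0 and vec.pnn50 == 0
        assert vec.sd1 == 0 and vec.sd2 == 0
        assert vec.vlf == pytest.approx(0, abs=1e-9)
        assert np.isnan(vec.lf_hf)

    def test_generator_parameter_recovery(self):
        from vtapredict.synthetic import GeneratorParams, generate_rr_series

        params = GeneratorParams(mean_nn=684.45, noise_sd=30, seed=4, lf_amp=20, hf_amp=20)
        series = generate_rr_series(params)
        vec = extract_features(series)
        se = 30 / np.sqrt(len(series))
        assert abs(vec.mean_nn - 684.45) < 3 * se + 0.2  # sinusoids average out

    def test_pure_function_unaffected_by_trailing_interval_roundtrip(self, rng):
        x = rng.uniform(600, 1000, 400)
        before = extract_features(x).as_array()
        appended = np.append(x, 750.0)[:-1]
        after = extract_features(appended).as_array()
        assert np.allclose(
            np.nan_to_num(before, nan=-1), np.nan_to_num(after, nan=-1)
        )
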