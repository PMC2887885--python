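"""Feature extractors against brute-force oracles, plus matrix-level behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cuffeng.features as feat
from cuffeng.errors import DegenerateWindowError, InvalidConfigError, SchemaError
from cuffeng.features import (
    FeatureMatrix,
    FeatureSpec,
    acorr_min,
    ar_coeffs,
    cepstral_coeffs,
    dft_energy,
    hos2,
    hos3,
    mav,
    normalize_train_test,
    var_unbiased,
    waveform_length,
    wden,
    wden_threshold,
)
from cuffeng.preprocess import frame_windows
from cuffeng.types import LabeledRecording, WindowConfig

windows_50 = st.lists(
    st.floats(-100, 100, allow_nan=False, width=32), min_size=10, max_size=50
).map(lambda v: np.asarray(v, dtype=np.float64))


class TestScalarOracles:
    """Direct-formula brute force on small windows."""

    @pytest.mark.parametrize(
        "fn,oracle",
        [
            (mav, lambda x: sum(abs(v) for v in x) / len(x)),
            (var_unbiased, lambda x: sum((v - np.mean(x)) ** 2 for v in x) / (len(x) - 1)),
            (waveform_length, lambda x: sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))),
            (dft_energy, lambda x: sum(v**2 for v in x)),
        ],
    )
    def test_brute_force_equivalence(self, fn, oracle, rng):
        for _ in range(5):
            x = rng.standard_normal(rng.integers(4, 50))
            assert fn(x) == pytest.approx(oracle(x), abs=1e-9)

    def test_trivial_values(self):
        assert mav(np.zeros(8)) == 0.0
        assert mav(np.array([1.0, -1.0, 1.0, -1.0])) == 1.0
        assert var_unbiased(np.full(5, 3.0)) == 0.0
        assert var_unbiased(np.array([0.0, 2.0])) == 2.0
        assert waveform_length(np.full(6, 2.0)) == 0.0
        assert waveform_length(np.array([0.0, 1.0, 0.0, 1.0])) == 3.0
        assert dft_energy(np.zeros(16)) == 0.0

    def test_degenerate_windows_rejected(self):
        with pytest.raises(DegenerateWindowError):
            var_unbiased(np.array([1.0]))
        with pytest.raises(DegenerateWindowError):
            mav(np.array([]))

    @settings(deadline=None, max_examples=25)
    @given(x=windows_50, a=st.floats(-10, 10, allow_nan=False))
    def test_homogeneity_laws(self, x, a):
        """MAV and WL scale linearly, VAR and DFT quadratically."""
        assert mav(a * x) == pytest.approx(abs(a) * mav(x), abs=1e-9, rel=1e-9)
        assert waveform_length(a * x) == pytest.approx(
            abs(a) * waveform_length(x), abs=1e-9, rel=1e-9
        )
        assert var_unbiased(a * x) == pytest.approx(
            a**2 * var_unbiased(x), abs=1e-9, rel=1e-9
        )
        assert dft_energy(a * x) == pytest.approx(a**2 * dft_energy(x), abs=1e-9, rel=1e-9)

    def test_parseval_identity(self, rng):
        x = rng.standard_normal(100)
        assert dft_energy(x) == pytest.approx(np.sum(x**2), abs=1e-9)


class TestWden:
    def test_zero_window(self):
        assert wden(np.zeros(256)) == 0.0

    def test_threshold_formula_n2048(self):
        assert wden_threshold(1.0, 2048) == pytest.approx(0.3936 + 0.1829 * 11)

    def test_burst_survives_noise_does_not(self, rng):
        noise = rng.standard_normal(2048)
        burst = noise.copy()
        burst[1000:1100] += 10.0 * np.sin(2 * np.pi * np.arange(100) / 12)
        assert wden(burst) > wden(noise)

    def test_window_too_short_for_level(self):
        with pytest.raises(InvalidConfigError):
            wden(np.zeros(8), level=4)


class TestArCeps:
    def test_ar1_parameter_recovery(self, rng):
        """x[n] = 0.8 x[n-1] + e -> polynomial coefficient a_1 ~ -0.8."""
        e = rng.standard_normal(2000)
        x = np.empty(2000)
        x[0] = e[0]
        for i in range(1, 2000):
            x[i] = 0.8 * x[i - 1] + e[i]
        a = ar_coeffs(x, order=1)
        assert a[0] == pytest.approx(-0.8, abs=0.05)

    def test_white_noise_coefficients_near_zero(self, rng):
        a = ar_coeffs(rng.standard_normal(2000), order=2)
        assert np.all(np.abs(a) < 0.05)

    def test_matches_normal_equation_oracle(self, rng):
        """Explicit forward-backward normal-equation solve on a 50-sample window."""
        x = rng.standard_normal(50)
        p = 3
        rows, targets = [], []
        for s in (x, x[::-1]):
            for t in range(p, 50):
                rows.append([s[t - 1], s[t - 2], s[t - 3]])
                targets.append(s[t])
        phi, *_ = np.linalg.lstsq(np.array(rows), np.array(targets), rcond=None)
        assert np.allclose(ar_coeffs(x, p), -phi, atol=1e-6)

    def test_too_short_window_rejected(self):
        with pytest.raises(DegenerateWindowError):
            ar_coeffs(np.zeros(8), order=4)

    def test_ceps_first_coefficient(self):
        assert cepstral_coeffs(np.array([0.5]))[0] == -0.5

    def test_ceps_zero_in_zero_out(self):
        assert np.array_equal(cepstral_coeffs(np.zeros(4)), np.zeros(4))

    def test_ceps_matches_log_series_oracle(self, rng):
        """c_m are the power-series coefficients of -log A(z) (FFT cepstrum)."""
        a = np.array([0.3, -0.2, 0.1])
        nfft = 1024
        poly = np.zeros(nfft)
        poly[0] = 1.0
        poly[1 : 1 + a.size] = a
        chat = -np.fft.ifft(np.log(np.fft.fft(poly))).real
        assert np.allclose(cepstral_coeffs(a), chat[1 : 1 + a.size], atol=1e-9)


class TestHos:
    def test_white_noise_small_spread(self, rng):
        x = rng.standard_normal(2000)
        assert hos2(x) / np.mean(x**2) < 0.5

    def test_sinusoid_large_spread(self):
        x = np.sin(2 * np.pi * 1500 * np.arange(2000) / 20_000)
        assert hos2(x) / np.mean(x**2) > 0.9

    def test_hos_zero_window(self):
        assert hos2(np.zeros(100)) == 0.0
        assert hos3(np.zeros(100)) == 0.0

    def test_hos_dimension_validation(self):
        with pytest.raises(InvalidConfigError):
            hos2(np.zeros(100), m=1)
        with pytest.raises(InvalidConfigError):
            hos3(np.zeros(100), m=1)

    def test_hos3_gaussian_below_skewed_burst(self, rng):
        gauss = rng.standard_normal(2000)
        skewed = rng.standard_normal(2000) ** 2 - 1.0  # zero-mean, skewed
        skewed *= gauss.std() / skewed.std()  # equalize power
        assert hos3(gauss) < hos3(skewed)

    def test_hos3_matches_triple_product_oracle(self, rng):
        """Brute-force C3(tau, tau) + SVD on a 30-sample window."""
        x = rng.standard_normal(30)
        m = 5
        c3 = np.zeros(m)
        for tau in range(m):
            c3[tau] = sum(x[i] * x[i + tau] * x[i + tau] for i in range(30 - tau)) / 30
        T = np.array([[c3[abs(i - j)] for j in range(m)] for i in range(m)])
        expected = np.linalg.svd(T, compute_uv=False)[0]
        assert hos3(x, m=m) == pytest.approx(expected, abs=1e-9)


class TestAcorr:
    def test_cosine_first_minimum(self):
        # period 20 samples on a 2000-sample window -> minimum ~ -1 near lag 10
        x = np.cos(2 * np.pi * np.arange(2000) / 20)
        assert acorr_min(x) == pytest.approx(-1.0, abs=0.05)

    def test_white_noise_minimum_small(self, rng):
        v = acorr_min(rng.standard_normal(2000))
        assert -0.2 < v < 0.0

    def test_normalization_r0_is_one(self, rng):
        from cuffeng.features import _autocorr_biased

        x = rng.standard_normal(500)
        r = _autocorr_biased(x, x.size)
        assert r[0] / r[0] == 1.0
        assert np.all(np.abs(r / r[0]) <= 1.0 + 1e-12)


class TestMatrixLevel:
    def _frames(self, rng, n_windows=4, win=256):
        x = rng.standard_normal(n_windows * win)
        rec = LabeledRecording(x, 20_000.0, [])
        return frame_windows(rec, WindowConfig(row_ms=win / 20.0))

    def test_multi_sets_expand(self, rng):
        frames = self._frames(rng)
        fm2 = feat.extract_features(frames, FeatureSpec(names=("MULTI2",)))
        assert fm2.feature_names == ("MAV", "VAR", "WL")
        fm4 = feat.extract_features(frames, FeatureSpec(names=("MULTI4",)))
        assert fm4.feature_names == ("MAV", "WL", "HOS3")

    def test_vector_features_expand_to_order_columns(self, rng):
        frames = self._frames(rng)
        fm = feat.extract_features(frames, FeatureSpec(names=("AR", "CEPS"), ar_order=4))
        assert fm.feature_names == tuple(
            f"{n}{i}" for n in ("AR", "CEPS") for i in range(1, 5)
        )

    def test_identical_windows_identical_rows(self, rng):
        w = rng.standard_normal(256)
        rec = LabeledRecording(np.concatenate([w, w]), 20_000.0, [])
        frames = frame_windows(rec, WindowConfig(row_ms=256 / 20.0))
        fm = feat.extract_features(frames, FeatureSpec(names=("MULTI3", "WDEN", "ACORR")))
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_normalization_train_max_is_one(self, rng):
        frames = self._frames(rng, n_windows=6)
        fm = feat.extract_features(frames, FeatureSpec(names=("MULTI2",)))
        train = FeatureMatrix(fm.values[:3], fm.feature_names, fm.window_labels[:3], fm.window_times[:3])
        test = FeatureMatrix(fm.values[3:], fm.feature_names, fm.window_labels[3:], fm.window_times[3:])
        tr, te = normalize_train_test(train, test)
        assert np.allclose(np.max(np.abs(tr.values), axis=0), 1.0)
        # test columns use the training constants
        assert np.allclose(te.values, test.values / tr.normalization_constants)

    def test_known_constant_scaling(self):
        names = ("F",)
        train = FeatureMatrix(np.array([[5.0], [-2.0]]), names, np.array(["a", "b"], dtype=object), np.array([0.0, 1.0]))
        test = FeatureMatrix(np.array([[7.0]]), names, np.array(["a"], dtype=object), np.array([2.0]))
        _, te = normalize_train_test(train, test)
        assert te.values[0, 0] == pytest.approx(1.4)

    def test_zero_column_warns_and_passes_through(self):
        names = ("F",)
        lbl = np.array(["a", "b"], dtype=object)
        train = FeatureMatrix(np.zeros((2, 1)), names, lbl, np.array([0.0, 1.0]))
        test = FeatureMatrix(np.ones((2, 1)), names, lbl, np.array([2.0, 3.0]))
        with pytest.warns(UserWarning):
            tr, te = normalize_train_test(train, test)
        assert np.array_equal(tr.values, train.values)
        assert np.array_equal(te.values, test.values)

    def test_column_mismatch_rejected(self):
        lbl = np.array(["a"], dtype=object)
        t0 = np.array([0.0])
        a = FeatureMatrix(np.ones((1, 1)), ("X",), lbl, t0)
        b = FeatureMatrix(np.ones((1, 1)), ("Y",), lbl, t0)
        with pytest.raises(SchemaError):
            normalize_train_test(a, b)

    def test_stimulus_windows_exceed_rest_in_power_features(self, filtered_proprio):
        """Median MAV/VAR/WL/DFT over stimulus windows beats rest at ~3.8 dB."""
        frames = frame_windows(filtered_proprio, WindowConfig(row_ms=100.0))
        fm = feat.extract_features(frames, FeatureSpec(names=("MULTI3",)))
        stim = fm.window_labels == "proprio"
        rest = fm.window_labels == "rest"
        for j, name in enumerate(fm.feature_names):
            assert np.median(fm.values[stim, j]) > np.median(fm.values[rest, j]), name
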