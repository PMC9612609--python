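"""MSC estimation: spectra, coherence bounds, band averaging, feature layout."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sg

from cmcsel.coherence import (
    DEFAULT_BANDS,
    band_average,
    build_feature_matrix,
    cross_spectra,
    feature_index,
    feature_unmap,
    msc,
    msc_pooled,
    n_welch_windows,
)

FS = 500.0


def welch_oracle(x, y, fs=FS, win_len=0.5, nfft=256, overlap=0.5):
    """Averaged windowed-periodogram products straight from the definition."""
    nper = int(round(win_len * fs))
    step = nper - int(nper * overlap)
    w = sg.get_window("hann", nper)
    scale = 1.0 / (fs * np.sum(w ** 2))
    starts = list(range(0, len(x) - nper + 1, step))
    Sxx = np.zeros(nfft // 2 + 1)
    Syy = np.zeros(nfft // 2 + 1)
    Sxy = np.zeros(nfft // 2 + 1, dtype=complex)
    for s in starts:
        X = np.fft.rfft(x[s:s + nper] * w, nfft)
        Y = np.fft.rfft(y[s:s + nper] * w, nfft)
        Sxx += np.abs(X) ** 2
        Syy += np.abs(Y) ** 2
        Sxy += np.conj(X) * Y
    for S in (Sxx, Syy, Sxy):
        S *= scale / len(starts)
        S[1:-1] *= 2.0  # one-sided
    return Sxx, Syy, Sxy


class TestCrossSpectra:
    def test_self_cross_spectrum_equals_autospectrum(self):
        x = np.random.default_rng(0).standard_normal(2000)
        _, sxx, _, sxy = cross_spectra(x, x, FS)
        np.testing.assert_allclose(sxy.real, sxx, atol=1e-12)
        np.testing.assert_allclose(sxy.imag, 0.0, atol=1e-12)

    def test_cauchy_schwarz_bound_on_delayed_copy(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        y = np.roll(x, 17)
        _, sxx, syy, sxy = cross_spectra(x, y, FS)
        assert np.all(np.abs(sxy) ** 2 <= sxx * syy * (1 + 1e-9))

    def test_matches_direct_definition_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(2000), rng.standard_normal(2000)
        _, sxx, syy, sxy = cross_spectra(x, y, FS)
        oxx, oyy, oxy = welch_oracle(x, y)
        np.testing.assert_allclose(sxx, oxx, rtol=1e-9)
        np.testing.assert_allclose(syy, oyy, rtol=1e-9)
        np.testing.assert_allclose(sxy, oxy, rtol=1e-9)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            cross_spectra(np.zeros(100), np.zeros(100), FS)  # < 0.5 s window


class TestMsc:
    def test_identical_signals_have_unit_coherence(self):
        x = np.random.default_rng(3).standard_normal(2000)
        _, c = msc(x, x, FS)
        assert np.all(c > 1 - 1e-9)

    def test_lti_filtered_copy_keeps_high_coherence(self):
        # a noiseless LTI relationship has unit coherence; estimate it where
        # the filter response is flat so window leakage cannot bite
        rng = np.random.default_rng(4)
        x = rng.standard_normal(4000)
        fir = sg.firwin(7, 0.8)  # short + flat: negligible window-edge transients
        y = sg.lfilter(fir, 1.0, x)
        f, c = msc(x[2000:], y[2000:], FS)
        band = (f > 5) & (f < 80)
        assert np.all(c[band] >= 0.99)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(2000), rng.standard_normal(2000)
        _, c1 = msc(x, y, FS)
        _, c2 = msc(5.0 * x, 0.2 * y, FS)
        np.testing.assert_allclose(c1, c2, rtol=1e-9)

    def test_independent_noise_bias_near_one_over_windows(self):
        # overlapped Welch windows are correlated, so the bias sits slightly
        # above 1/W_overlapped but below 1/W for non-overlapping windows
        means = []
        for s in range(50):
            rng = np.random.default_rng(100 + s)
            _, c = msc(rng.standard_normal(2000), rng.standard_normal(2000), FS)
            means.append(c.mean())
        mean = float(np.mean(means))
        w_overlap = n_welch_windows(2000, FS)
        w_disjoint = 2000 // 250
        assert mean <= 1.0 / w_disjoint
        assert mean == pytest.approx(1.0 / w_overlap, rel=0.15)


class TestPooledMsc:
    def test_pooled_estimator_shrinks_for_independent_noise(self):
        rng = np.random.default_rng(6)
        xs = rng.standard_normal((20, 2000))
        ys = rng.standard_normal((20, 2000))
        _, c_pooled = msc_pooled(xs, ys, FS)
        _, c_single = msc(xs[0], ys[0], FS)
        assert c_pooled.mean() < c_single.mean()


class TestBandAverage:
    def test_constant_spectrum_maps_to_constant_bands(self):
        f = np.linspace(0, FS / 2, 129)
        out = band_average(f, np.full(129, 0.5))
        np.testing.assert_allclose(out, 0.5)

    def test_indicator_spectrum_isolates_alpha(self):
        f = np.linspace(0, FS / 2, 129)
        spec = ((f >= 8) & (f < 13)).astype(float)
        out = band_average(f, spec)
        names = DEFAULT_BANDS.names
        assert out[names.index("alpha")] == 1.0
        assert out[names.index("delta")] == 0.0

    def test_full_band_matches_direct_loop(self):
        rng = np.random.default_rng(7)
        f = np.linspace(0, FS / 2, 129)
        spec = rng.uniform(size=129)
        out = band_average(f, spec)
        direct = np.mean([s for fi, s in zip(f, spec) if 1.5 <= fi <= 80.0])
        assert out[DEFAULT_BANDS.names.index("full")] == pytest.approx(direct, rel=1e-12)

    def test_empty_band_is_an_error(self):
        f = np.linspace(0, FS / 2, 5)  # 62.5 Hz spacing: delta has no bin
        with pytest.raises(ValueError, match="delta"):
            band_average(f, np.ones(5))

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_band_means_stay_within_spectrum_bounds(self, a, b):
        lo, hi = min(a, b), max(a, b)
        f = np.linspace(0, FS / 2, 129)
        rng = np.random.default_rng(8)
        spec = rng.uniform(lo, hi + 1e-12, size=129)
        out = band_average(f, spec)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-9)


class TestFeatureIndex:
    def test_first_and_last_columns(self):
        assert feature_index(1, 1, 1, 5, 32, 11) == 0
        assert feature_index(5, 32, 11, 5, 32, 11) == 1759

    def test_bijection_on_random_triples(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            m, q, k = rng.integers(1, 6), rng.integers(1, 33), rng.integers(1, 12)
            col = feature_index(m, q, k, 5, 32, 11)
            assert feature_unmap(col, 5, 32, 11) == (m, q, k)

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            feature_index(0, 1, 1, 5, 32, 11)
        with pytest.raises(IndexError):
            feature_unmap(1760, 5, 32, 11)


class TestFeatureMatrix:
    def test_tiny_layout_column_count_and_band_order(self, tiny_features):
        fm = tiny_features
        assert fm.n_features == fm.M * fm.Q * 11
        assert fm.column_triple(0) == (fm.emg_labels[0], fm.eeg_labels[0], "delta")

    def test_values_are_coherences_in_unit_interval(self, tiny_features):
        assert np.all(tiny_features.values >= 0.0)
        assert np.all(tiny_features.values <= 1.0)

    def test_matches_bruteforce_per_pair_loops(self, tiny_bundle):
        fm = build_feature_matrix(tiny_bundle)
        for n in (0, 1):
            for m in range(tiny_bundle.n_emg):
                for q in range(tiny_bundle.n_eeg):
                    f, c = msc(tiny_bundle.emg_segments[n, m],
                               tiny_bundle.eeg_segments_by_emg[m, n, q],
                               tiny_bundle.fs)
                    expected = band_average(f, c)
                    cols = [fm.feature_index(m + 1, q + 1, k + 1) for k in range(11)]
                    np.testing.assert_allclose(fm.values[n, cols], expected, rtol=1e-9)

    def test_planted_coupling_column_has_top_contrast(self, tiny_dataset, tiny_features):
        _, gt = tiny_dataset
        fm = tiny_features
        labels = fm.labels
        contrast = np.abs(fm.values[labels == 1].mean(0) - fm.values[labels == 2].mean(0))
        assert int(np.argmax(contrast)) == gt.discriminative_columns[0]

    def test_unrectified_bundle_rejected(self, tiny_bundle):
        from dataclasses import replace
        with pytest.raises(ValueError):
            build_feature_matrix(replace(tiny_bundle, rectified=False))
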