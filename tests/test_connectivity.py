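"""wPLI estimator: cross-spectra, per-definition oracle, null behaviour
and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taugraph.connectivity import (ConnectivityMatrix, cross_spectra,
                                   subject_adjacency, wpli_band, wpli_matrix)
from taugraph.preprocess import bandpass, epoch_recording, rereference_average
from taugraph.synthetic import CohortConfig, simulate_subject_eeg
from .conftest import make_epochs

FS = 256.0


def _sine_epochs(freq, lag_samples=0, n=int(20 * FS)):
    t = np.arange(n) / FS
    s = np.sin(2 * np.pi * freq * t)
    return make_epochs(np.stack([s, np.roll(s, lag_samples)])[None], FS, 20.0)


def wpli_oracle(segments: np.ndarray, freqs: np.ndarray,
                band: tuple[float, float]) -> np.ndarray:
    """Direct per-definition wPLI for one epoch.

    ``segments``: (n_segments, n_channels, n_samples) raw segments; the
    oracle applies the Hamming taper and FFT itself and then loops plainly
    over pairs, segments and frequency bins.
    """
    from scipy.signal import get_window

    K, C, nper = segments.shape
    win = get_window("hamming", nper)
    spectra = [[np.fft.rfft(segments[k, c] * win) for c in range(C)]
               for k in range(K)]
    bins = [b for b, f in enumerate(freqs) if band[0] <= f <= band[1]]
    W = np.zeros((C, C))
    for i in range(C):
        for j in range(C):
            if i == j:
                continue
            per_bin = []
            for b in bins:
                imx = [np.imag(spectra[k][i][b] * np.conj(spectra[k][j][b]))
                       for k in range(K)]
                num = abs(sum(imx))
                den = sum(abs(v) for v in imx)
                per_bin.append(num / den if den > 0 else 0.0)
            W[i, j] = np.mean(per_bin)
    return W


class TestCrossSpectra:
    def test_segment_count_79(self, rng):
        ep = make_epochs(rng.standard_normal((1, 2, int(20 * FS))), FS, 20.0)
        cs = cross_spectra(ep, window_s=0.5, overlap_frac=0.5)
        assert cs.n_segments == 79

    def test_self_cross_spectrum_real(self, rng):
        ep = make_epochs(rng.standard_normal((1, 3, int(20 * FS))), FS, 20.0)
        cs = cross_spectra(ep)
        x = cs.cross(1, 1)
        assert np.abs(x.imag).max() < 1e-9 * np.abs(x.real).max()

    def test_lagged_sine_phase(self):
        lag = 5
        cs = cross_spectra(_sine_epochs(8.0, lag))
        x = cs.cross(0, 1)  # channel 1 is channel 0 delayed by `lag`
        b = int(np.argmin(np.abs(cs.frequencies - 8.0)))
        phases = np.angle(x[0, :, b])
        expected = 2 * np.pi * 8.0 * lag / FS
        assert np.abs(np.angle(np.exp(1j * (phases - expected)))).max() < 0.05

    def test_too_few_segments_rejected(self, rng):
        ep = make_epochs(rng.standard_normal((1, 2, 128)), FS, 0.5)
        with pytest.raises(ValueError):
            cross_spectra(ep, window_s=0.5)


class TestWpli:
    def test_lagged_common_sinusoid_is_one(self):
        # 3-sample lag at 10 Hz: constant nonzero phase lag at the carrier
        mats = wpli_band(cross_spectra(_sine_epochs(10.0, 3)), (10.0, 10.0))
        assert mats[0].W[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_identical_signals_zero(self):
        mats = wpli_band(cross_spectra(_sine_epochs(10.0, 0)), (10.0, 10.0))
        assert mats[0].W[0, 1] == 0.0

    def test_independent_noise_near_null_level(self, rng):
        vals = [wpli_matrix(make_epochs(
            rng.standard_normal((1, 2, int(20 * FS))), FS, 20.0),
            (8.0, 13.0)).W[0, 1] for _ in range(200)]
        mean = np.mean(vals)
        assert 0.05 < mean < 0.25  # ~1/sqrt(pi*K/2) scale at K=79

    def test_matches_per_definition_oracle(self, rng):
        # 3 channels x 4 segments (1.25 s epoch, 0.5 s window, 50% overlap)
        n = int(1.25 * FS)
        data = rng.standard_normal((1, 3, n))
        ep = make_epochs(data, FS, 1.25)
        cs = cross_spectra(ep)
        assert cs.n_segments == 4
        vec = wpli_band(cs, (8.0, 13.0))[0].W
        nper = int(0.5 * FS)
        step = nper // 2
        segs = np.stack([data[0][:, k * step:k * step + nper]
                         for k in range(4)])
        ref = wpli_oracle(segs, cs.frequencies, (8.0, 13.0))
        np.testing.assert_allclose(vec, ref, atol=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((1, 3, int(2 * FS)))
        base = wpli_matrix(make_epochs(data, FS, 2.0), (8.0, 13.0)).W
        data2 = data.copy()
        data2[0, 1] *= scale
        scaled = wpli_matrix(make_epochs(data2, FS, 2.0), (8.0, 13.0)).W
        np.testing.assert_allclose(scaled, base, atol=1e-12)

    def test_zero_lag_mixing_does_not_inflate(self):
        """Instantaneous (volume-conduction-like) mixing must not raise the
        band wPLI above the Monte-Carlo null's 95th percentile."""
        def mean_offdiag(zero_lag_amp, seeds):
            out = []
            for seed in seeds:
                cfg = CohortConfig(seed=0, n_channels=8, duration_s=100,
                                   fs=128, coupling_base=0.0, theta_amp=0.0,
                                   zero_lag_amp=zero_lag_amp)
                rec = simulate_subject_eeg(cfg, 0.0, 7000 + seed)
                ep = epoch_recording(bandpass(rereference_average(rec),
                                              0.5, 40.0))
                W = wpli_matrix(ep, (8.0, 13.0)).W
                out.append(W[np.triu_indices(8, 1)].mean())
            return np.array(out)

        null = mean_offdiag(0.0, range(20))
        confound = mean_offdiag(25.0, range(20, 30))
        assert confound.mean() < np.quantile(null, 0.95)


class TestSubjectAdjacency:
    def _mat(self, w, labels=("a", "b", "c")):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = w
        return ConnectivityMatrix(W=W, channel_labels=list(labels))

    def test_identical_epochs_average_to_same(self):
        mats = [self._mat(0.4)] * 12
        avg = subject_adjacency(mats)
        np.testing.assert_allclose(avg.W, mats[0].W)
        assert avg.n_epochs == 12

    def test_alternating_edge_averages_to_half(self):
        mats = [self._mat(1.0), self._mat(0.0)] * 3
        assert subject_adjacency(mats).W[0, 1] == pytest.approx(0.5)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            subject_adjacency([self._mat(0.1), self._mat(0.1, ("a", "b", "z"))])

    def test_averaging_shrinks_null_variance(self, rng):
        singles, averaged = [], []
        for _ in range(40):
            mats = wpli_band(cross_spectra(make_epochs(
                rng.standard_normal((12, 2, int(5 * FS))), FS, 5.0)),
                (8.0, 13.0))
            singles.append(mats[0].W[0, 1])
            averaged.append(subject_adjacency(mats).W[0, 1])
        ratio = np.var(averaged) / np.var(singles)
        assert ratio < 0.3  # ~1/12 in theory; generous Monte-Carlo bound


class TestInvariants:
    def test_wpli_bounds_on_synthetic_recording(self):
        cfg = CohortConfig(seed=0, n_channels=8, duration_s=100, fs=128)
        rec = simulate_subject_eeg(cfg, 0.5, 3)
        ep = epoch_recording(bandpass(rereference_average(rec), 0.5, 40.0))
        for m in wpli_band(cross_spectra(ep), (8.0, 13.0)):
            assert (m.W >= 0).all() and (m.W <= 1).all()
            np.testing.assert_allclose(m.W, m.W.T, atol=1e-12)
            assert np.all(np.diag(m.W) == 0)


class TestDebiasedEstimator:
    def test_bounded_and_high_for_lagged_pair(self):
        cs = cross_spectra(_sine_epochs(10.0, 3))
        W = wpli_band(cs, (10.0, 10.0), debiased=True)[0].W
        assert 0.99 < W[0, 1] <= 1.0

    def test_null_level_below_plain_estimator(self, rng):
        plain, db = [], []
        for _ in range(60):
            ep = make_epochs(rng.standard_normal((1, 2, int(10 * FS))), FS, 10.0)
            cs = cross_spectra(ep)
            plain.append(wpli_band(cs, (8.0, 13.0))[0].W[0, 1])
            db.append(wpli_band(cs, (8.0, 13.0), debiased=True)[0].W[0, 1])
        # bias correction pulls the null toward zero
        assert np.mean(db) < np.mean(plain)
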