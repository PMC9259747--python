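import numpy as np
import pytest

from eegevt.features import CWTConfig, awp, cwt_morlet, dawp, extract_features, wavelet_power
from eegevt.preprocess import Segmentation, segment
from eegevt.recording import Recording

from conftest import BAND_CWT


def _morlet_time(t, freq, w0=6.0):
    """Time-domain analytic Morlet matching the package's spectral kernel."""
    s = w0 / (2 * np.pi * freq)
    return (2.0 / (s * np.sqrt(2 * np.pi))) * np.exp(-(t**2) / (2 * s**2)) * np.exp(1j * w0 * t / s)


def test_zero_signal_gives_zero_wp():
    rec = Recording(signal=np.zeros((2, 128 * 10)), fs=128.0)
    W = wavelet_power(rec, CWTConfig(freq_range=(1, 10), n_freqs=10))
    assert np.all(W == 0)


def test_sinusoid_peak_frequency_and_flatness():
    fs, f0 = 128.0, 3.0
    t = np.arange(int(60 * fs)) / fs
    rec = Recording(signal=np.sin(2 * np.pi * f0 * t)[None, :], fs=fs)
    cfg = CWTConfig(freq_range=(1, 10), n_freqs=19)
    W = wavelet_power(rec, cfg)[0]
    mid = slice(int(10 * fs), -int(10 * fs))
    profile = W[:, mid].mean(axis=1)
    assert cfg.freqs[np.argmax(profile)] == pytest.approx(f0)
    ridge = W[np.argmax(profile), mid]
    assert np.ptp(ridge) / ridge.mean() < 0.05
    # amplitude-normalized: unit sinusoid has WP ~ 1 at its own frequency
    assert ridge.mean() == pytest.approx(1.0, rel=1e-6)


def test_cwt_matches_direct_numerical_integration(rng):
    """Oracle: Riemann-sum convolution with the time-domain Morlet wavelet."""
    fs, f0 = 64.0, 3.0
    n = int(40 * fs)
    x = rng.standard_normal(n)
    W = cwt_morlet(x, fs, np.array([f0]))[0, 0]
    tt = np.arange(-10 * fs, 10 * fs + 1) / fs
    psi = _morlet_time(tt, f0)
    for t0_idx in [int(15 * fs), int(20 * fs), int(25 * fs)]:
        taus = np.arange(n) / fs
        t0 = t0_idx / fs
        oracle = np.sum(x * np.interp(t0 - taus, tt, psi.real)) / fs + 1j * np.sum(
            x * np.interp(t0 - taus, tt, psi.imag)
        ) / fs
        assert W[t0_idx] == pytest.approx(oracle, rel=1e-6)


def test_wp_scales_linearly_with_amplitude():
    fs = 128.0
    t = np.arange(int(30 * fs)) / fs
    x = np.sin(2 * np.pi * 4 * t)
    cfg = CWTConfig(freq_range=(2, 6), n_freqs=9)
    W1 = wavelet_power(Recording(signal=x[None, :], fs=fs), cfg)
    W3 = wavelet_power(Recording(signal=3.5 * x[None, :], fs=fs), cfg)
    np.testing.assert_allclose(W3, 3.5 * W1, rtol=1e-7, atol=1e-12)


def test_cwt_agrees_with_pywavelets_oracle():
    """Independent route: pywt's complex Morlet at the same center frequency."""
    pywt = pytest.importorskip("pywt")
    fs, f0 = 128.0, 4.0
    t = np.arange(int(30 * fs)) / fs
    x = np.sin(2 * np.pi * f0 * t) + 0.3 * np.sin(2 * np.pi * 9.0 * t)
    freqs = np.array([4.0, 9.0])  # the two frequencies actually present
    ours = np.abs(cwt_morlet(x, fs, freqs))[0]
    fc = 6.0 / (2 * np.pi)
    scales = fc * fs / freqs
    theirs, _ = pywt.cwt(x, scales, f"cmor2.0-{fc}", sampling_period=1 / fs)
    theirs = np.abs(theirs)
    mid = slice(int(5 * fs), -int(5 * fs))
    ratios = []
    for i in range(len(freqs)):
        a, b = ours[i, mid], theirs[i, mid]
        # time profiles at each frequency agree after rescaling by the
        # (frequency-dependent) normalization constant between conventions
        np.testing.assert_allclose(a / a.mean(), b / b.mean(), atol=0.03)
        ratios.append(a.mean() / b.mean() * np.sqrt(scales[i]))
    # amplitude (L1) vs pywt's L2 normalization differ by sqrt(scale)
    assert ratios[0] == pytest.approx(ratios[1], rel=0.02)


def test_awp_normalization_constant_band():
    cfg = CWTConfig(freq_range=(1, 10), n_freqs=19, band_F=(2, 5))
    n_band = len(cfg.band_freqs)
    assert n_band == 7
    W = np.full((1, 19, 100), 0.0)
    W[:, :, :] = 4.2  # constant over every frequency
    E = awp(W, cfg)
    np.testing.assert_allclose(E, 4.2, rtol=1e-12)


def test_awp_is_channel_mean():
    cfg = CWTConfig(freq_range=(1, 10), n_freqs=19, band_F=(2, 5))
    W = np.zeros((2, 19, 50))
    W[0] = 1.0
    W[1] = 3.0
    np.testing.assert_allclose(awp(W, cfg), 2.0, rtol=1e-12)


def test_awp_requires_band_coverage():
    # a 2-point grid at 1 and 10 Hz has no points inside the 2-5 Hz band
    sparse = CWTConfig(freq_range=(1, 10), n_freqs=2, band_F=(2, 5))
    with pytest.raises(ValueError, match="band_F"):
        awp(np.zeros((1, 2, 10)), sparse)


def test_dawp_equals_per_interval_sample_mean(rng):
    fs = 128.0
    seg = Segmentation(M=5, interval_s=60.0)
    E = rng.random(int(5.6 * 60 * fs))
    e = dawp(E, seg, fs)
    step = int(60 * fs)
    for m in range(5):
        assert e[m] == pytest.approx(E[m * step:(m + 1) * step].mean(), rel=1e-9)


def test_dawp_simple_cases():
    seg = Segmentation(M=2, interval_s=60.0)
    fs = 2.0
    E = np.r_[np.full(120, 1.0), np.full(120, 3.0)]
    np.testing.assert_allclose(dawp(E, seg, fs), [1.0, 3.0])
    np.testing.assert_allclose(dawp(np.full(240, 5.0), seg, fs), [5.0, 5.0])


def test_extract_features_matches_unfused_path(short_recording):
    seg = segment(short_recording)
    feats = extract_features(short_recording, BAND_CWT, seg)
    W = wavelet_power(short_recording, BAND_CWT)
    E_ref = awp(W, BAND_CWT)
    np.testing.assert_allclose(feats.E, E_ref, rtol=1e-4)
    np.testing.assert_allclose(feats.e, dawp(E_ref, seg, short_recording.fs), rtol=1e-4)
    assert np.all(feats.E >= 0) and np.all(feats.e >= 0)
    assert len(feats.e) == seg.M


def test_scale_covariance_and_channel_permutation(short_recording):
    seg = segment(short_recording)
    feats = extract_features(short_recording, BAND_CWT, seg)
    scaled = short_recording.with_signal(short_recording.signal * 2.5)
    feats2 = extract_features(scaled, BAND_CWT, seg)
    np.testing.assert_allclose(feats2.e, 2.5 * feats.e, rtol=1e-5)
    perm = short_recording.with_signal(short_recording.signal[::-1].copy())
    feats3 = extract_features(perm, BAND_CWT, seg)
    np.testing.assert_allclose(feats3.E, feats.E, rtol=1e-5)


def test_frequency_grid_outside_nyquist_rejected():
    rec = Recording(signal=np.zeros((1, 1280)), fs=128.0)
    with pytest.raises(ValueError):
        wavelet_power(rec, CWTConfig(freq_range=(1, 70), n_freqs=10, band_F=(2, 5)))
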