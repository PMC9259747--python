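"""Wavelet band-power features: WP, channel/band-averaged AWP, interval DAWP.

Wavelet power is the modulus (not squared modulus) of Morlet continuous
wavelet transform coefficients.  The transform is computed in the Fourier
domain with an analytic Morlet kernel, amplitude-normalized so that a unit
sinusoid yields WP = 1 at its own frequency.  AWP ``E(t)`` averages WP over
the 2-5 Hz band (trapezoid rule on the frequency grid, divided by the band
width) and over channels; DAWP ``e_m`` is the time average of ``E(t)`` over
each 60-s interval.  All three are nonnegative and scale linearly with
signal amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .preprocess import Segmentation
from .recording import Recording


@dataclass
class CWTConfig:
    """Time-frequency analysis settings.

    ``freq_range``/``n_freqs`` define the transform grid (1-30 Hz at 0.5 Hz
    by default), ``band_F`` the averaging band; ``morlet_w0`` is the Morlet
    center parameter (time-frequency resolution trade-off).  ``single``
    computes in complex64, halving FFT cost on hour-scale recordings.
    """

    freq_range: tuple[float, float] = (1.0, 30.0)
    band_F: tuple[float, float] = (2.0, 5.0)
    n_freqs: int = 59
    morlet_w0: float = 6.0
    single_precision: bool = False

    def __post_init__(self) -> None:
        f0, f1 = self.freq_range
        b0, b1 = self.band_F
        if not 0 < f0 < f1:
            raise ValueError("freq_range must satisfy 0 < low < high")
        if not (f0 <= b0 < b1 <= f1):
            raise ValueError("band_F must be a nonempty sub-range of freq_range")
        if self.n_freqs < 2:
            raise ValueError("n_freqs must be at least 2")

    @property
    def freqs(self) -> np.ndarray:
        return np.linspace(*self.freq_range, self.n_freqs)

    @property
    def band_freqs(self) -> np.ndarray:
        f = self.freqs
        b0, b1 = self.band_F
        return f[(f >= b0 - 1e-9) & (f <= b1 + 1e-9)]

    @property
    def delta_F(self) -> float:
        return self.band_F[1] - self.band_F[0]


@dataclass
class FeatureSeries:
    """Per-recording AWP time series and per-interval DAWP values."""

    E: np.ndarray                 # AWP, one value per sample, power units
    e: np.ndarray                 # DAWP, length M
    fs: float
    segmentation: Segmentation
    meta: dict = field(default_factory=dict)


def _morlet_kernel_ft(freq: float, w0: float, omega: np.ndarray) -> np.ndarray:
    """Fourier transform of the analytic Morlet wavelet centered at `freq`.

    Normalized so that the modulus of the transform of a unit-amplitude
    sinusoid at `freq` equals 1.
    """
    s = w0 / (2 * np.pi * freq)
    out = np.zeros_like(omega)
    pos = omega > 0
    out[pos] = 2.0 * np.exp(-0.5 * (s * omega[pos] - w0) ** 2)
    return out


def cwt_morlet(
    x: np.ndarray, fs: float, freqs: np.ndarray, w0: float = 6.0, single: bool = False
) -> np.ndarray:
    """Complex Morlet CWT coefficients, shape ``x.shape[:-1] + (n_freqs, n)``."""
    x = np.atleast_2d(x)
    n = x.shape[-1]
    nfft = sfft.next_fast_len(n + int(4 * fs))
    cdtype = np.complex64 if single else np.complex128
    X = sfft.fft(x.astype(np.float32 if single else np.float64), nfft, axis=-1)
    omega = 2 * np.pi * sfft.fftfreq(nfft, 1.0 / fs)
    out = np.empty(x.shape[:-1] + (len(freqs), n), dtype=cdtype)
    for i, f in enumerate(freqs):
        H = _morlet_kernel_ft(float(f), w0, omega).astype(cdtype)
        out[..., i, :] = sfft.ifft(X * H, axis=-1)[..., :n]
    return out


def wavelet_power(rec: Recording, cfg: CWTConfig | None = None) -> np.ndarray:
    """WP(channel, frequency, time) = |Morlet CWT coefficients|.

    For long recordings prefer :func:`extract_features`, which never
    materializes the full time-frequency cube.
    """
    cfg = cfg or CWTConfig()
    freqs = cfg.freqs
    if freqs[0] <= 0 or freqs[-1] >= rec.fs / 2:
        raise ValueError(
            f"frequency grid [{freqs[0]}, {freqs[-1]}] Hz outside (0, {rec.fs / 2}) Hz"
        )
    return np.abs(
        cwt_morlet(rec.signal, rec.fs, freqs, cfg.morlet_w0, cfg.single_precision)
    )


def awp(W: np.ndarray, cfg: CWTConfig | None = None) -> np.ndarray:
    """Band- and channel-averaged wavelet power E(t).

    ``W`` has shape (n_channels, n_freqs, n_samples) on the config's full
    frequency grid; the integral over the band is a trapezoid rule divided
    by the band width, then averaged over channels.
    """
    cfg = cfg or CWTConfig()
    freqs = cfg.freqs
    band = cfg.band_freqs
    if len(band) < 2:
        raise ValueError("band_F not covered by the frequency grid")
    idx = np.isin(np.round(freqs, 9), np.round(band, 9))
    Wb = W[..., idx, :]
    integral = np.trapezoid(Wb, band, axis=-2)
    return integral.mean(axis=0) / cfg.delta_F


def dawp(E: np.ndarray, seg: Segmentation, fs: float) -> np.ndarray:
    """Time-average of E(t) over each 60-s interval (sample mean)."""
    step = int(round(seg.interval_s * fs))
    if seg.M * step > len(E):
        raise ValueError("E does not cover all segmentation intervals")
    trimmed = E[: seg.M * step]
    return trimmed.reshape(seg.M, step).mean(axis=1)


def extract_features(
    rec: Recording, cfg: CWTConfig | None = None, seg: Segmentation | None = None
) -> FeatureSeries:
    """Full feature pipeline for one recording, streaming over channels.

    Equivalent to ``dawp(awp(wavelet_power(rec)))`` but accumulates the
    band integral channel by channel so memory stays O(n_samples).
    """
    from .preprocess import PreprocessConfig, segment

    cfg = cfg or CWTConfig()
    if seg is None:
        seg = segment(rec, PreprocessConfig())
    band = cfg.band_freqs
    if len(band) < 2:
        raise ValueError("band_F not covered by the frequency grid")
    if band[0] <= 0 or band[-1] >= rec.fs / 2:
        raise ValueError("frequency band outside (0, fs/2)")

    n = rec.n_samples
    nfft = sfft.next_fast_len(n + int(4 * rec.fs))
    cdtype = np.complex64 if cfg.single_precision else np.complex128
    rdtype = np.float32 if cfg.single_precision else np.float64
    omega = 2 * np.pi * sfft.fftfreq(nfft, 1.0 / rec.fs)
    weights = np.zeros(len(band))
    df = np.diff(band)
    weights[:-1] += df / 2
    weights[1:] += df / 2  # trapezoid weights over the band grid

    E = np.zeros(n)
    kernels = [
        _morlet_kernel_ft(float(f), cfg.morlet_w0, omega).astype(cdtype) for f in band
    ]
    for ch in range(rec.n_channels):
        X = sfft.fft(rec.signal[ch].astype(rdtype), nfft)
        for wgt, H in zip(weights, kernels):
            E += wgt * np.abs(sfft.ifft(X * H)[:n])
    E /= rec.n_channels * cfg.delta_F
    e = dawp(E, seg, rec.fs)
    return FeatureSeries(
        E=E,
        e=e,
        fs=rec.fs,
        segmentation=seg,
        meta={
            "band_F": cfg.band_F,
            "delta_F": cfg.delta_F,
            "morlet_w0": cfg.morlet_w0,
            "n_channels": rec.n_channels,
            "freqs": band.tolist(),
            "interval_s": seg.interval_s,
        },
    )
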