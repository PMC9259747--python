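"""Synthetic long-term EEG with planted seizures and ground-truth marking.

The generator emulates the statistical structure that the downstream
analysis relies on, not seizure morphology: per-channel 1/f background
with a shared alpha rhythm and a slow vigilance-state amplitude drift,
plus rare 30-120 s episodes during which 2-5 Hz band amplitude rises by a
configurable gain coherently on all channels.  With a large gain the
60-s band-power distribution acquires a heavy (sub-exponential) tail with
the seizures in it; with a weak gain the tail stays near-exponential,
emulating recordings on which tail-based detection fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import CHANNELS_1020_25, Interval, Marking, Recording

#: nominal background RMS in microvolts; every downstream statistic is
#: scale-covariant, so absolute calibration is cosmetic.
BACKGROUND_RMS_UV = 10.0

#: distribution of seizure counts in cohort builders; long-term monitoring
#: patients have one to five seizures, most often a single one.
SEIZURE_COUNT_PROBS = (0.40, 0.30, 0.15, 0.10, 0.05)


@dataclass
class SynthConfig:
    """Configuration of one synthetic recording.

    Parameters
    ----------
    duration
        Recording length in seconds (>= 120).
    n_channels, fs
        Montage size and sampling rate; defaults mirror 25-channel,
        128 Hz clinical long-term monitoring.
    n_seizures
        Number of planted seizure episodes (0-5).
    seizure_dur_range
        Seizure duration bounds in seconds.
    seizure_gain
        Multiplicative 2-5 Hz amplitude factor during seizures.  When
        ``None`` it resolves from ``tail_mode``: 8.0 for ``"heavy"``
        (seizures are extreme tail events), 1.5 for ``"exponential"``
        (seizures too weak to leave the bulk of the distribution).
    artifact_rate
        Brief (<2 s) transient artifacts per hour.
    amp_scale
        Overall amplitude multiplier (subject-specific baseline).
    tail_mode
        ``"heavy"`` or ``"exponential"``; see ``seizure_gain``.
    seed
        Seed for all randomness in the recording.
    """

    duration: float
    n_channels: int = 25
    fs: float = 128.0
    n_seizures: int = 1
    seizure_dur_range: tuple[float, float] = (30.0, 120.0)
    seizure_gain: float | None = None
    artifact_rate: float = 6.0
    slow_artifact_rate: float = 1.25
    slow_artifact_gain: tuple[float, float] = (1.5, 3.5)
    amp_scale: float = 1.0
    tail_mode: str = "heavy"
    alpha_amp: float = 3.0
    modulation_sd: float = 0.25
    modulation_tau_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tail_mode not in ("heavy", "exponential"):
            raise ValueError("tail_mode must be 'heavy' or 'exponential'")
        if self.seizure_gain is None:
            self.seizure_gain = 8.0 if self.tail_mode == "heavy" else 1.5
        if self.duration < 120:
            raise ValueError("duration must be at least 120 s")
        if not 0 <= self.n_seizures <= 5:
            raise ValueError("n_seizures must be between 0 and 5")
        lo, hi = self.seizure_dur_range
        if not 0 < lo <= hi:
            raise ValueError("seizure_dur_range must satisfy 0 < low <= high")
        if self.tail_mode == "heavy" and self.seizure_gain <= 1:
            raise ValueError("seizure_gain must exceed 1 in heavy tail mode")
        if self.n_channels < 1 or self.fs <= 0:
            raise ValueError("n_channels and fs must be positive")
        if self.n_seizures * hi >= 0.5 * self.duration:
            raise ValueError(
                "seizures must be rare events: total possible seizure time "
                f"({self.n_seizures} x {hi} s) reaches 50% of the recording"
            )

    @property
    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels <= len(CHANNELS_1020_25):
            return CHANNELS_1020_25[: self.n_channels]
        extra = tuple(f"EEG{i}" for i in range(len(CHANNELS_1020_25), self.n_channels))
        return CHANNELS_1020_25 + extra


def _colored_noise(
    rng: np.random.Generator, n_ch: int, n: int, fs: float, exponent: float = 1.0,
    f_knee: float = 1.0,
) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent spectrum above ``f_knee`` Hz,
    flat below it, unit RMS per channel.

    Flattening the spectrum below the knee keeps the total power from
    being dominated by a handful of ultra-slow Fourier modes, whose
    realization-to-realization variance would otherwise make the
    normalized band amplitude swing severalfold between seeds.
    """
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f_eff = np.maximum(f, f_knee)
    spec *= f_eff ** (-exponent / 2.0)
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms


def _slow_envelope(rng: np.random.Generator, cfg: SynthConfig, n: int) -> np.ndarray:
    """Lognormal vigilance-state amplitude drift, generated on a 1 Hz grid."""
    n_coarse = max(int(np.ceil(cfg.duration)) + 1, 8)
    sigma = max(cfg.modulation_tau_s, 1.0)
    z = rng.standard_normal(n_coarse + int(6 * sigma))
    kernel_t = np.arange(-3 * sigma, 3 * sigma + 1)
    kernel = np.exp(-0.5 * (kernel_t / sigma) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(z, kernel, mode="same")[: n_coarse]
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd * cfg.modulation_sd
    t_coarse = np.arange(n_coarse)
    t_full = np.arange(n) / cfg.fs
    return np.exp(np.interp(t_full, t_coarse, smooth))


def _draw_seizure_intervals(rng: np.random.Generator, cfg: SynthConfig) -> list[tuple[float, float]]:
    """Non-overlapping seizure spans with edge margins, by rejection sampling."""
    lo, hi = cfg.seizure_dur_range
    margin, gap = 30.0, 60.0
    spans: list[tuple[float, float]] = []
    attempts = 0
    while len(spans) < cfg.n_seizures:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place non-overlapping seizures; recording too short")
        dur = rng.uniform(lo, min(hi, cfg.duration / 2))
        start = rng.uniform(margin, cfg.duration - margin - dur)
        if all(start + dur + gap <= s or e + gap <= start for s, e in spans):
            spans.append((start, start + dur))
    return sorted(spans)


def _band_rms(x: np.ndarray, fs: float, band: tuple[float, float] = (2.0, 5.0)) -> np.ndarray:
    """Per-channel RMS of the band-passed signal, estimated on a short chunk."""
    n_probe = min(x.shape[1], int(600 * fs))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    probe = sps.sosfiltfilt(sos, x[:, :n_probe], axis=1)
    return np.sqrt(np.mean(probe**2, axis=1))


def _raised_cosine_window(n_total: int, n_ramp_on: int, n_ramp_off: int) -> np.ndarray:
    win = np.ones(n_total)
    if n_ramp_on > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp_on) / n_ramp_on))
        win[:n_ramp_on] = r
    if n_ramp_off > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp_off) / n_ramp_off))
        win[-n_ramp_off:] = r[::-1]
    return win


def generate_recording(cfg: SynthConfig) -> Recording:
    """Generate one synthetic recording with ground-truth marking.

    The same config and seed always produce the identical signal matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration * fs))
    n_ch = cfg.n_channels

    # 1/f background, per-channel independent, plus shared 10 Hz rhythm.
    x = _colored_noise(rng, n_ch, n, fs) * BACKGROUND_RMS_UV
    alpha_src = rng.standard_normal(n)
    sos_alpha = sps.butter(2, (9.0, 11.0), btype="bandpass", fs=fs, output="sos")
    alpha = sps.sosfiltfilt(sos_alpha, alpha_src)
    alpha /= max(np.sqrt(np.mean(alpha**2)), 1e-12)
    alpha_gain = rng.uniform(0.5, 1.5, size=(n_ch, 1))
    x += cfg.alpha_amp * alpha_gain * alpha[None, :]

    # band RMS measured on the unmodulated background, so the seizure gain
    # is relative to the local (envelope-scaled) background level
    sigma_band = _band_rms(x, fs)

    envelope = _slow_envelope(rng, cfg, n)
    x *= envelope[None, :]

    # planted seizures: coherent band-limited 2-5 Hz oscillation, amplitude
    # calibrated so in-seizure band power ~ gain^2 x local background power
    spans = _draw_seizure_intervals(rng, cfg) if cfg.n_seizures else []
    gain = float(cfg.seizure_gain)
    add_amp = np.sqrt(max(gain**2 - 1.0, 0.0))
    sos_seiz = sps.butter(4, (2.0, 5.0), btype="bandpass", fs=fs, output="sos")
    intervals = []
    for start_s, end_s in spans:
        i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
        pad = int(2 * fs)
        src = rng.standard_normal(i1 - i0 + 2 * pad)
        wav = sps.sosfiltfilt(sos_seiz, src)[pad:-pad]
        wav /= max(np.sqrt(np.mean(wav**2)), 1e-12)
        n_on = int(rng.uniform(1.0, 2.0) * fs)
        n_off = int(rng.uniform(1.0, 2.0) * fs)
        win = _raised_cosine_window(i1 - i0, n_on, n_off)
        ch_gain = rng.uniform(0.8, 1.2, size=(n_ch, 1))
        local_env = envelope[i0:i1]
        x[:, i0:i1] += (add_amp * sigma_band[:, None] * ch_gain) * (wav * win * local_env)[None, :]
        intervals.append(Interval(start_s, end_s, "seizure"))

    # slow artifact episodes (movement / failing electrode): tens of seconds
    # of moderately elevated low-frequency power on a random channel subset.
    # These populate the band-power distribution between the bulk and the
    # seizure extremes, the way real long-term recordings teem with
    # non-seizure outliers (which is why clinical precision is low)
    n_slow = rng.poisson(cfg.slow_artifact_rate * cfg.duration / 3600.0)
    sos_slow = sps.butter(4, (1.0, 5.0), btype="bandpass", fs=fs, output="sos")
    for _ in range(n_slow):
        dur = rng.uniform(10.0, 60.0)
        t0 = rng.uniform(1.0, cfg.duration - dur - 1.0)
        i0, i1 = int(t0 * fs), int((t0 + dur) * fs)
        gain_slow = rng.uniform(*cfg.slow_artifact_gain)
        add = np.sqrt(max(gain_slow**2 - 1.0, 0.0))
        pad = int(2 * fs)
        src = rng.standard_normal(i1 - i0 + 2 * pad)
        wav = sps.sosfiltfilt(sos_slow, src)[pad:-pad]
        wav /= max(np.sqrt(np.mean(wav**2)), 1e-12)
        n_ramp = int(1.0 * fs)
        win = _raised_cosine_window(i1 - i0, n_ramp, n_ramp)
        chans = rng.choice(n_ch, size=max(1, n_ch // 2), replace=False)
        local_env = envelope[i0:i1]
        x[chans, i0:i1] += (add * sigma_band[chans, None] * rng.uniform(0.7, 1.3, (len(chans), 1))
                            ) * (wav * win * local_env)[None, :]
        intervals.append(Interval(t0, t0 + dur, "artifact"))

    # brief transient artifacts with per-recording fixed topographies, as
    # real ocular/myogenic sources have (this is what makes them separable
    # by ICA): a bilateral frontal blink pattern and one broadband pattern
    # over a random but fixed channel subset
    n_art = rng.poisson(cfg.artifact_rate * cfg.duration / 3600.0)
    rms = BACKGROUND_RMS_UV
    blink_topo = np.zeros(n_ch)
    if n_ch >= 2:
        blink_topo[0], blink_topo[1] = 1.0, rng.uniform(0.85, 1.15)
    subset = rng.choice(n_ch, size=min(n_ch, int(rng.integers(2, 5))), replace=False)
    burst_topo = np.zeros(n_ch)
    burst_topo[subset] = rng.uniform(0.5, 1.0, size=len(subset))
    for _ in range(n_art):
        t0 = rng.uniform(1.0, cfg.duration - 3.0)
        dur = rng.uniform(0.2, 1.5)
        i0, i1 = int(t0 * fs), int((t0 + dur) * fs)
        amp = rng.uniform(8, 20) * rms
        if rng.random() < 0.5 and n_ch >= 2:
            lobe = amp * np.sin(np.pi * np.arange(i1 - i0) / (i1 - i0))
            x[:, i0:i1] += blink_topo[:, None] * lobe[None, :]
        else:
            burst = amp * 0.5 * rng.standard_normal(i1 - i0)
            x[:, i0:i1] += burst_topo[:, None] * burst[None, :]
        intervals.append(Interval(t0, t0 + dur, "artifact"))

    marking = Marking(tuple(intervals))
    x *= cfg.amp_scale
    return Recording(
        signal=x,
        fs=fs,
        channel_labels=cfg.channel_labels,
        marking=marking,
        log={"synth_config": cfg},
    )


@dataclass
class CohortSpec:
    """Specification of a homogeneous synthetic cohort."""

    n_subjects: int
    duration: float
    tail_mode: str = "heavy"
    n_channels: int = 25
    seizure_gain: float | None = None
    artifact_rate: float = 6.0
    subject_amp_sd: float = 0.0
    seed: int = 0
    synth_overrides: dict = field(default_factory=dict)


def cohort_configs(spec: CohortSpec) -> list[SynthConfig]:
    """Per-subject configs for a cohort; subject i of two cohorts that differ
    only in ``tail_mode``/``seizure_gain`` shares seed and seizure layout,
    enabling paired comparisons."""
    root = np.random.default_rng(spec.seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=spec.n_subjects)
    cfgs = []
    for i in range(spec.n_subjects):
        meta_rng = np.random.default_rng(sub_seeds[i])
        n_seiz = 1 + int(meta_rng.choice(5, p=SEIZURE_COUNT_PROBS))
        amp = float(np.exp(meta_rng.normal(0.0, spec.subject_amp_sd))) if spec.subject_amp_sd else 1.0
        cfgs.append(
            SynthConfig(
                duration=spec.duration,
                n_channels=spec.n_channels,
                n_seizures=n_seiz,
                seizure_gain=spec.seizure_gain,
                artifact_rate=spec.artifact_rate,
                amp_scale=amp,
                tail_mode=spec.tail_mode,
                seed=int(sub_seeds[i]),
                **spec.synth_overrides,
            )
        )
    return cfgs


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    return [generate_recording(cfg) for cfg in cohort_configs(spec)]
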