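"""Filtering, ICA-based artifact removal, and 60-s segmentation.

Filtering is zero-phase (forward-backward IIR): a 4th-order Butterworth
band-pass at 1-60 Hz plus a quality-30 notch at 50 Hz by default, applied
channel-wise.  Artifact removal decomposes the recording with FastICA and
zeroes components that look artifactual; the rejection rule targets brief
transients (blinks, electrode pops) and deliberately spares sustained
oscillatory events, which is what the detector must keep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.decomposition import FastICA

from .recording import Recording


@dataclass
class PreprocessConfig:
    bandpass: tuple[float, float] = (1.0, 60.0)
    notch: float = 50.0
    notch_q: float = 30.0
    ica_enabled: bool = True
    ica_kurtosis_thresh: float = 8.0
    ica_frontal_corr_thresh: float = 0.8
    ica_max_transient_s: float = 2.0
    ica_seed: int = 0
    ica_fit_samples: int = 120_000
    interval_s: float = 60.0

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        if not 0 < lo < hi:
            raise ValueError("bandpass must satisfy 0 < low < high")
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")


@dataclass(frozen=True)
class Segmentation:
    """Contiguous half-open intervals of length ``interval_s`` starting at 0.

    ``M = floor(L / interval_s)``; a trailing remainder shorter than one
    interval is discarded, never padded.
    """

    M: int
    interval_s: float

    @property
    def interval_bounds(self) -> list[tuple[float, float]]:
        return [(m * self.interval_s, (m + 1) * self.interval_s) for m in range(self.M)]

    def sample_slices(self, fs: float) -> list[slice]:
        step = int(round(self.interval_s * fs))
        return [slice(m * step, (m + 1) * step) for m in range(self.M)]


def filter_recording(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Zero-phase band-pass + notch, channel-wise; marking passes through."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.bandpass
    if rec.fs <= 2 * hi:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for band-pass high cutoff {hi} Hz"
        )
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    if cfg.notch and cfg.notch < rec.fs / 2:
        b, a = sps.iirnotch(cfg.notch, cfg.notch_q, fs=rec.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    return rec.with_signal(out, filter=dict(bandpass=cfg.bandpass, notch=cfg.notch))


def _is_artifact_component(
    source: np.ndarray, frontal: np.ndarray | None, cfg: PreprocessConfig, fs: float
) -> tuple[bool, str]:
    """Classify one independent component time series as artifactual.

    Two routes flag a component: (a) heavy-tailed AND transient -- excess
    kurtosis above threshold with supra-4-sigma excursions lasting under
    ``ica_max_transient_s`` (brief pops/blinks; sustained oscillatory events
    such as seizures also raise kurtosis but fail the brevity check and are
    kept); (b) bilateral frontal projection -- absolute correlation above
    threshold with BOTH channels of the frontal pair (ocular artifacts are
    bilateral, genuine unilateral frontal EEG is not flagged).
    """
    # classification statistics tolerate decimation; keep >= 32 Hz so the
    # envelope still resolves sub-second transients
    dec = max(1, int(fs // 32))
    if dec > 1:
        source = source[::dec]
        if frontal is not None:
            frontal = frontal[:, ::dec]
        fs = fs / dec
    kurt = stats.kurtosis(source, fisher=True)
    if kurt > cfg.ica_kurtosis_thresh:
        # excursion durations measured on a smoothed RMS envelope, so an
        # oscillatory event counts as one long run, not many zero-crossing
        # fragments
        win = max(int(0.25 * fs), 1)
        power = sps.convolve(source**2, np.ones(win) / win, mode="same")
        env = np.sqrt(np.maximum(power, 0.0))
        above = env > 4.0 * np.median(env)
        if above.any():
            edges = np.diff(above.astype(int))
            starts = np.flatnonzero(edges == 1) + 1
            ends = np.flatnonzero(edges == -1) + 1
            if above[0]:
                starts = np.r_[0, starts]
            if above[-1]:
                ends = np.r_[ends, len(above)]
            runs_s = (ends - starts) / fs
            # conservative: one sustained excursion protects the component;
            # components carrying any seizure-like event are never removed
            if runs_s.max() < cfg.ica_max_transient_s:
                return True, f"kurtosis={kurt:.1f}, transient"
    if frontal is not None:
        corrs = [abs(np.corrcoef(source, chan)[0, 1]) for chan in frontal]
        if len(corrs) == 2 and min(corrs) > cfg.ica_frontal_corr_thresh:
            return True, f"frontal corr={min(corrs):.2f}"
    return False, ""


def remove_artifacts_ica(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """FastICA decomposition; artifactual components zeroed, rest reconstructed.

    The unmixing matrix is estimated on a strided subsample (at most
    ``ica_fit_samples`` points) and applied to the full recording.  On
    decomposition failure the recording passes through unchanged with a
    warning, so the detector always runs.
    """
    cfg = cfg or PreprocessConfig()
    if not cfg.ica_enabled:
        return rec.with_signal(rec.signal, ica=dict(enabled=False, removed=[]))
    if rec.n_channels < 2:
        raise ValueError("ICA requires at least 2 channels")
    x = rec.signal
    stride = max(1, x.shape[1] // cfg.ica_fit_samples)
    fit_x = x[:, ::stride].T
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(
                n_components=rec.n_channels,
                whiten="unit-variance",
                random_state=cfg.ica_seed,
                max_iter=500,
            )
            ica.fit(fit_x)
        sources = ica.transform(x.T).T  # (n_components, n_samples)
    except Exception as exc:  # decomposition failure must not kill the pipeline
        warnings.warn(f"ICA decomposition failed ({exc}); passing recording through")
        return rec.with_signal(rec.signal, ica=dict(enabled=True, removed=[], failed=True))

    labels = [lbl.lower() for lbl in rec.channel_labels]
    frontal_idx = [i for i, lbl in enumerate(labels) if lbl in ("fp1", "fp2")]
    frontal = x[frontal_idx] if len(frontal_idx) == 2 else None

    candidates = []
    for k in range(sources.shape[0]):
        bad, why = _is_artifact_component(sources[k], frontal, cfg, rec.fs)
        if bad:
            candidates.append((float(stats.kurtosis(sources[k])), k, why))
    # safety cap: never strip more than a third of the decomposition
    cap = max(1, rec.n_channels // 3)
    candidates.sort(reverse=True)
    removed = [k for _, k, _ in candidates[:cap]]
    reasons = [why for _, _, why in candidates[:cap]]
    keep = sources.copy()
    for k in removed:
        keep[k] = 0.0
    recon = (keep.T @ ica.mixing_.T + ica.mean_).T
    return rec.with_signal(
        recon, ica=dict(enabled=True, removed=removed, reasons=reasons)
    )


def segment(rec: Recording, cfg: PreprocessConfig | None = None) -> Segmentation:
    """Divide the recording into M = floor(L / interval_s) intervals."""
    cfg = cfg or PreprocessConfig()
    L = rec.duration
    if L < cfg.interval_s:
        raise ValueError(
            f"recording ({L:.1f} s) shorter than one interval ({cfg.interval_s} s)"
        )
    return Segmentation(M=int(L // cfg.interval_s), interval_s=cfg.interval_s)
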