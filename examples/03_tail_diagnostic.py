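"""Weibull tail diagnostic: will outlier detection work on this patient?

Band power during seizures lives in the far tail of the interval
distribution.  When the above-95th-percentile exceedances follow a heavy
Weibull law (shape c < 1), seizures are genuine extreme events and an
outlier detector is credible; a near-exponential tail (c >= 1) predicts
failure.  Here the same subject is simulated in both regimes.
"""

from eegevt import SynthConfig, extreme_report, generate_recording
from eegevt.features import CWTConfig, extract_features
from eegevt.preprocess import filter_recording, remove_artifacts_ica, segment

cwt = CWTConfig(freq_range=(2, 5), n_freqs=7, single_precision=True)
for mode in ("heavy", "exponential"):
    cfg = SynthConfig(duration=28800, n_channels=6, n_seizures=2,
                      tail_mode=mode, seed=3)
    rec = remove_artifacts_ica(filter_recording(generate_recording(cfg)))
    feats = extract_features(rec, cwt, segment(rec))
    rep = extreme_report(feats, series="e")
    gof = "n/a" if rep.gof is None else f"{rep.gof.p:.3f}"
    print(f"{mode:12s} gain={cfg.seizure_gain}: shape c = {rep.fit.c:.2f} "
          f"(tail n = {rep.n_tail}, chi-square p = {gof}) -> "
          f"{'HEAVY tail, detector credible' if rep.heavy_tailed else 'light tail, detector not credible'}")
# Strong seizures drive c well below 1; weak ones leave the tail close to
# exponential, reproducing the split between detectable and undetectable
# patients.
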