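"""Generate a synthetic long-term EEG recording and inspect its marking.

The generator plants 30-120 s seizures (2-5 Hz band amplitude raised by a
configurable gain) into 1/f background with a shared alpha rhythm, slow
amplitude drift, and both brief and slow artifacts.
"""

import numpy as np

from eegevt import SynthConfig, generate_recording

cfg = SynthConfig(duration=3600, n_channels=6, n_seizures=2, seizure_gain=8.0, seed=1)
rec = generate_recording(cfg)

print(f"recording: {rec.n_channels} channels x {rec.duration:.0f} s at {rec.fs:.0f} Hz")
print(f"background RMS ~ {np.sqrt(np.mean(rec.signal ** 2)):.1f} uV")
for iv in rec.marking:
    print(f"  {iv.label:8s} {iv.start_s:7.1f} - {iv.end_s:7.1f} s")
# The seizure rows are the ground truth the detector is later scored
# against; artifact rows are confounders it should ignore.
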