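"""Generate a gamma-interval noise-burst stream and check its statistics.

The stimulus is an ongoing train of narrowband noise bursts whose
inter-burst intervals come from a gamma law with mean 1/rate and SD
equal to the irregularity. The fixed preset is 4 bursts/s with 31 ms
irregularity at 10 kHz, 70 dB SPL.
"""

import numpy as np

from soundseek.stimulus import FIXED_PRESET, make_train, render_stream

rng = np.random.default_rng(0)
train = make_train(FIXED_PRESET, duration=30.0, rng=rng)
wave = render_stream(train, sample_rate=48_000, rng=rng)

intervals = np.diff(train.onsets)
print(f"bursts in 30 s        : {len(train.onsets)} (expected ~120 at 4/s)")
print(f"mean interval         : {intervals.mean()*1000:.1f} ms "
      "(expected 250 ms)")
print(f"interval SD           : {intervals.std(ddof=1)*1000:.1f} ms "
      "(the 'irregularity', expected ~31 ms)")
print(f"waveform RMS          : {np.sqrt(np.mean(wave**2)):.4f} full-scale "
      "(bursts at 70 dB SPL re 94 dB full-scale sine, mostly silence)")
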