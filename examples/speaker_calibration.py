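"""Fit and apply a per-frequency speaker calibration.

During calibration the received spectrum of white noise is measured and
the dB correction needed at each frequency to reach a flat spectrum is
computed, then applied to stimuli in software before playback.
"""

import numpy as np
from scipy import signal

from soundseek.stimulus import (apply_calibration, fit_calibration,
                                measure_spectrum_db)

fs = 96_000
rng = np.random.default_rng(0)
# Emulate a speaker with a sloped response: a 2-pole low-pass at 25 kHz.
sos = signal.butter(2, 25_000, btype="lowpass", fs=fs, output="sos")
measured = signal.sosfilt(sos, rng.standard_normal(fs * 8))

grid_khz = np.linspace(5, 20, 61)
level_db = measure_spectrum_db(measured, fs, grid_khz)
curve = fit_calibration(grid_khz, level_db)
print(f"correction range: {curve.gain_db.min():+.2f} to "
      f"{curve.gain_db.max():+.2f} dB over 5-20 kHz")

corrected = apply_calibration(measured, curve, fs)
flat_db = measure_spectrum_db(corrected, fs, grid_khz)
print(f"residual ripple after correction: "
      f"{flat_db.max() - flat_db.min():.2f} dB "
      f"(was {level_db.max() - level_db.min():.2f} dB)")
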