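"""Gamma-renewal burst-train stimuli and speaker calibration.

The auditory stimulus is an ongoing stream of narrowband noise bursts.
Inter-burst intervals are drawn i.i.d. from a gamma distribution
parameterized by its mean mu = 1/rate (the repetition rate in bursts/s)
and its standard deviation sigma (the "irregularity", in ms). This is the
unique gamma parameterization that lets rate and irregularity be varied
independently: shape k = (mu/sigma)^2, scale theta = sigma^2/mu.

Two stimulus regimes are supported:

- ``fixed`` preset: 10 kHz center frequency, 3 kHz bandwidth, 10 ms burst
  duration, 70 dB SPL, 4 bursts/s, 31 ms irregularity.
- ``variable``: per-trial draws of center frequency (5-15 kHz), level
  (65-90 dB SPL), rate (3-10 Hz) and irregularity (1-100 ms).

Digital level convention: a full-scale sine corresponds to ``DB_FULL_SCALE``
dB SPL (default 94), so a burst at L dB SPL has RMS
``10**((L - DB_FULL_SCALE)/20) / sqrt(2)`` in full-scale units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "StimulusParams",
    "BurstTrain",
    "CalibrationCurve",
    "FIXED_PRESET",
    "VARIABLE_RANGES",
    "sample_intervals",
    "synth_burst",
    "render_stream",
    "sample_trial_params",
    "fit_calibration",
    "apply_calibration",
    "error_tritone",
    "write_wav",
]

#: dB SPL produced by a digital full-scale sine; configurable per call.
DB_FULL_SCALE = 94.0


@dataclass(frozen=True)
class StimulusParams:
    """Acoustic parameters of one trial's burst stream.

    center_freq and bandwidth in kHz, burst_duration in ms, level in
    dB SPL, rate in bursts/s, irregularity (SD of the inter-burst
    interval) in ms.
    """

    center_freq: float = 10.0
    bandwidth: float = 3.0
    burst_duration: float = 10.0
    level: float = 70.0
    rate: float = 4.0
    irregularity: float = 31.0

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be > 0")


FIXED_PRESET = StimulusParams()

#: (low, high) per-parameter ranges in the variable regime.
VARIABLE_RANGES = {
    "center_freq": (5.0, 15.0),   # kHz, log-uniform
    "level": (65.0, 90.0),        # dB SPL, uniform in dB
    "rate": (3.0, 10.0),          # bursts/s, log-uniform
    "irregularity": (1.0, 100.0), # ms, log-uniform
}


@dataclass(frozen=True)
class BurstTrain:
    """Realized burst onset times (s) within [0, duration)."""

    onsets: np.ndarray
    params: StimulusParams
    duration: float

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if onsets[0] < 0 or onsets[-1] >= self.duration:
                raise ValueError("onsets must lie in [0, duration)")


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-frequency gain correction: frequencies in kHz, gain in dB."""

    frequencies: np.ndarray
    gain_db: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        g = np.asarray(self.gain_db, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "gain_db", g)
        if f.shape != g.shape:
            raise ValueError("frequencies and gain_db must match in shape")
        if not np.all(np.isfinite(g)):
            raise ValueError("gain_db must be finite")


def sample_intervals(rate, irregularity, duration, rng):
    """Draw inter-burst intervals from the (mean, SD) gamma model.

    Parameters
    ----------
    rate : float
        Bursts per second; the gamma mean is 1/rate.
    irregularity : float
        SD of the interval in **ms**. Zero gives the degenerate
        (perfectly periodic) limit.
    duration : float
        Stream duration in seconds; intervals are drawn until their
        cumulative sum would exceed it.
    rng : numpy.random.Generator or int seed

    Returns
    -------
    ndarray of intervals (s) whose cumulative sum is <= duration.
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if irregularity < 0:
        raise ValueError("irregularity must be >= 0")
    rng = np.random.default_rng(rng)
    mu = 1.0 / rate
    sigma = irregularity / 1000.0

    if sigma == 0.0:
        n = int(np.floor(duration / mu))
        return np.full(n, mu)

    shape = (mu / sigma) ** 2
    scale = sigma**2 / mu
    # Draw in chunks until the cumulative sum covers the duration.
    out = []
    total = 0.0
    n_guess = max(16, int(duration / mu * 1.5) + 8)
    while total <= duration:
        chunk = rng.gamma(shape, scale, size=n_guess)
        out.append(chunk)
        total += chunk.sum()
    intervals = np.concatenate(out)
    keep = np.searchsorted(np.cumsum(intervals), duration, side="right")
    return intervals[:keep]


def make_train(params: StimulusParams, duration, rng) -> BurstTrain:
    """Realize a burst train: onsets at the cumulative interval times."""
    intervals = sample_intervals(params.rate, params.irregularity, duration, rng)
    onsets = np.cumsum(intervals)
    onsets = onsets[onsets < duration]
    return BurstTrain(onsets=onsets, params=params, duration=float(duration))


def synth_burst(params: StimulusParams, sample_rate, rng,
                db_full_scale=DB_FULL_SCALE, ramp_ms=1.0):
    """Synthesize one narrowband noise burst.

    White noise is band-limited by a zero-phase Butterworth band-pass
    (center +/- bandwidth/2), shaped by raised-cosine on/off ramps, and
    RMS-scaled to ``params.level`` dB SPL under the full-scale-sine
    reference.
    """
    f_hi = (params.center_freq + params.bandwidth / 2.0) * 1000.0
    f_lo = (params.center_freq - params.bandwidth / 2.0) * 1000.0
    if sample_rate <= 2.0 * f_hi:
        raise ValueError(
            f"sample_rate {sample_rate} violates Nyquist for band edge {f_hi} Hz"
        )
    if f_lo <= 0:
        raise ValueError("bandwidth exceeds twice the center frequency")
    rng = np.random.default_rng(rng)
    n = int(round(params.burst_duration / 1000.0 * sample_rate))
    if n == 0:
        raise ValueError("burst_duration too short for this sample rate")

    # Filter with margin samples so edge transients fall outside the burst.
    pad = int(0.005 * sample_rate)
    noise = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(5, [f_lo, f_hi], btype="bandpass", fs=sample_rate,
                        output="sos")
    band = signal.sosfiltfilt(sos, noise)[pad:pad + n]

    n_ramp = min(int(round(ramp_ms / 1000.0 * sample_rate)), n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        band[:n_ramp] *= ramp
        band[-n_ramp:] *= ramp[::-1]

    rms_target = 10.0 ** ((params.level - db_full_scale) / 20.0) / np.sqrt(2.0)
    rms = np.sqrt(np.mean(band**2))
    if rms > 0:
        band *= rms_target / rms
    return band


def render_stream(train: BurstTrain, sample_rate, rng=0,
                  db_full_scale=DB_FULL_SCALE):
    """Render a burst train to a waveform: silence except bursts at onsets.

    Bursts whose intervals are shorter than the burst duration overlap;
    overlapping bursts are summed (with a warning) rather than truncated,
    preserving the train's interval statistics.
    """
    rng = np.random.default_rng(rng)
    n_total = int(round(train.duration * sample_rate))
    out = np.zeros(n_total)
    if train.onsets.size == 0:
        return out
    if np.any(np.diff(train.onsets) < train.params.burst_duration / 1000.0):
        warnings.warn("overlapping bursts summed (interval < burst duration)")
    for onset in train.onsets:
        burst = synth_burst(train.params, sample_rate, rng,
                            db_full_scale=db_full_scale)
        i0 = int(round(onset * sample_rate))
        i1 = min(i0 + burst.size, n_total)
        out[i0:i1] += burst[: i1 - i0]
    return out


def sample_trial_params(mode, rng) -> StimulusParams:
    """Draw one trial's stimulus parameters.

    ``fixed`` returns the fixed preset exactly. ``variable`` draws center
    frequency, rate and irregularity log-uniformly over their ranges and
    level uniformly in dB (the axes on which behavior is usually plotted).
    """
    if mode == "fixed":
        return FIXED_PRESET
    if mode != "variable":
        raise ValueError(f"mode must be 'fixed' or 'variable', got {mode!r}")
    rng = np.random.default_rng(rng)

    def log_uniform(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    lo, hi = VARIABLE_RANGES["level"]
    return StimulusParams(
        center_freq=log_uniform(*VARIABLE_RANGES["center_freq"]),
        level=float(rng.uniform(lo, hi)),
        rate=log_uniform(*VARIABLE_RANGES["rate"]),
        irregularity=log_uniform(*VARIABLE_RANGES["irregularity"]),
    )


def fit_calibration(frequencies_khz, power_db, target_db=None) -> CalibrationCurve:
    """Fit a per-frequency correction from a measured spectrum.

    gain_db[i] = target flat level - measured level at frequencies[i].
    With ``target_db=None`` the target is the mean measured level, so the
    correction is zero-mean.
    """
    f = np.asarray(frequencies_khz, dtype=float)
    p = np.asarray(power_db, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("measured spectrum must be finite (positive power)")
    if target_db is None:
        target_db = float(np.mean(p))
    return CalibrationCurve(frequencies=f, gain_db=target_db - p)


def measure_spectrum_db(waveform, sample_rate, frequencies_khz):
    """Welch power-spectral level (dB) interpolated onto a kHz grid."""
    nper = min(len(waveform), 4096)
    f, pxx = signal.welch(waveform, fs=sample_rate, nperseg=nper)
    if np.any(pxx <= 0):
        pxx = np.maximum(pxx, np.finfo(float).tiny)
    level = 10.0 * np.log10(pxx)
    return np.interp(np.asarray(frequencies_khz) * 1000.0, f, level)


def apply_calibration(waveform, curve: CalibrationCurve, sample_rate,
                      numtaps=511):
    """Apply a calibration curve via a linear-phase FIR equalizer.

    The FIR is designed by frequency sampling (``firwin2``) from the
    curve's dB gains; outside the curve's grid the gain is held at the
    edge values. Group delay is compensated so output aligns with input.
    """
    f_hz = curve.frequencies * 1000.0
    order = np.argsort(f_hz)
    f_hz, g_db = f_hz[order], curve.gain_db[order]
    nyq = sample_rate / 2.0
    freqs = np.concatenate([[0.0], f_hz, [nyq]])
    gains_db = np.concatenate([[g_db[0]], g_db, [g_db[-1]]])
    gains = 10.0 ** (gains_db / 20.0)
    fir = signal.firwin2(numtaps, freqs, gains, fs=sample_rate)
    out = signal.fftconvolve(waveform, fir, mode="full")
    delay = (numtaps - 1) // 2
    return out[delay:delay + len(waveform)]


def error_tritone(base_khz=8.0, duration_ms=250.0, sample_rate=192000,
                  level=70.0, db_full_scale=DB_FULL_SCALE):
    """Two-tone error sound: base frequency plus a tritone above it.

    Synthesis details of the behavioral rig's error sound are not
    modeled; this is a plain equal-amplitude pair at ``base`` and
    ``base * 2**(6/12)``.
    """
    n = int(round(duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    f0 = base_khz * 1000.0
    wave = np.sin(2 * np.pi * f0 * t) + np.sin(2 * np.pi * f0 * 2 ** 0.5 * t)
    rms_target = 10.0 ** ((level - db_full_scale) / 20.0) / np.sqrt(2.0)
    return wave * rms_target / np.sqrt(np.mean(wave**2))


def write_wav(path, waveform, sample_rate=192000, dtype="float32"):
    """Write a waveform to WAV (float32 or 16-bit PCM)."""
    from scipy.io import wavfile

    wave = np.asarray(waveform)
    if dtype == "float32":
        wavfile.write(path, int(sample_rate), wave.astype(np.float32))
    elif dtype == "int16":
        clipped = np.clip(wave, -1.0, 1.0)
        wavfile.write(path, int(sample_rate),
                      (clipped * 32767).astype(np.int16))
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")
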