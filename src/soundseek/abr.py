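"""Auditory brainstem response (ABR) preprocessing.

The ABR is a short-latency evoked potential recorded from skin
electrodes while brief clicks play from a speaker to the animal's left
or right. Raw recordings need four standard cleanup steps before the
averaged waveform is interpretable:

1. **Cross-talk removal** — the speaker drive voltage bleeds into the
   neural channel; the best least-squares FIR predicting neural voltage
   from speaker voltage is fit and its prediction subtracted.
2. **High-pass filtering** above 100 Hz (zero-phase) to remove drift.
3. **Outlier rejection** — epochs in the top 5% of peak-to-peak voltage
   excursion or of per-epoch SD (union of the two rules) are discarded.
4. **Polarity-corrected averaging** — kept epochs are averaged in a
   fixed window around each click; left-side responses are inverted so
   Wave 1 is positive regardless of speaker side.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, signal

__all__ = [
    "ABREpochSet",
    "ABRResult",
    "remove_crosstalk",
    "highpass",
    "extract_epochs",
    "reject_outliers",
    "average_abr",
    "preprocess_abr",
]

SAMPLE_RATE_HZ = 16_000
HIGHPASS_HZ = 100.0
FIR_TAPS = 32
#: Epoch window around each click trigger, in ms.
EPOCH_WINDOW_MS = (-2.0, 10.0)
OUTLIER_FRACTION = 0.05


@dataclass
class ABREpochSet:
    """A continuous paired recording plus click trigger indices.

    neural and speaker are voltage series (µV / V) of equal length
    sampled at ``sample_rate``; ``triggers`` holds click onset sample
    indices; ``side`` is the speaker side ('left' or 'right');
    ``level_dba`` the click level (60 or 70 dBA in the standard
    protocol).
    """

    neural: np.ndarray
    speaker: np.ndarray
    triggers: np.ndarray
    sample_rate: float = SAMPLE_RATE_HZ
    side: str = "right"
    level_dba: float = 70.0

    def __post_init__(self):
        self.neural = np.asarray(self.neural, dtype=float)
        self.speaker = np.asarray(self.speaker, dtype=float)
        self.triggers = np.asarray(self.triggers, dtype=int)
        if self.neural.shape != self.speaker.shape:
            raise ValueError("neural and speaker must have equal length")
        if self.triggers.size < 2:
            raise ValueError("need at least 2 epochs")
        if np.any(np.diff(self.triggers) <= 0):
            raise ValueError("triggers must be strictly increasing")
        if self.triggers[0] < 0 or self.triggers[-1] >= self.neural.size:
            raise ValueError("triggers out of range")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def n_epochs(self):
        return self.triggers.size


@dataclass
class ABRResult:
    """Averaged ABR waveform and the rejection bookkeeping."""

    waveform: np.ndarray
    time_ms: np.ndarray
    n_epochs_kept: int
    n_rejected: int
    polarity_applied: bool
    rejection_report: list = field(default_factory=list)


def remove_crosstalk(neural, speaker, filter_len=FIR_TAPS):
    """Subtract the least-squares FIR prediction of neural from speaker.

    A causal ``filter_len``-tap FIR is fit by least squares to predict
    the neural channel from the speaker channel; the prediction is then
    removed. As an orthogonal projection this can only reduce (never
    increase) residual power. A silent (zero-variance) speaker channel
    leaves the neural signal untouched.
    """
    neural = np.asarray(neural, dtype=float)
    speaker = np.asarray(speaker, dtype=float)
    if neural.shape != speaker.shape:
        raise ValueError("neural and speaker must have equal length")
    if filter_len < 1:
        raise ValueError("filter_len must be >= 1")
    if np.ptp(speaker) == 0:
        warnings.warn("speaker channel has zero variance; nothing to remove")
        return neural.copy()
    # Lagged (Toeplitz) design matrix: column j is speaker delayed j samples.
    first_col = speaker
    first_row = np.zeros(filter_len)
    first_row[0] = speaker[0]
    X = linalg.toeplitz(first_col, first_row)
    coef, *_ = np.linalg.lstsq(X, neural, rcond=None)
    return neural - X @ coef


def highpass(x, cutoff=HIGHPASS_HZ, sample_rate=SAMPLE_RATE_HZ, order=4):
    """Zero-phase Butterworth high-pass (default 100 Hz, 4th order)."""
    if cutoff >= sample_rate / 2.0:
        raise ValueError("cutoff must be below Nyquist")
    sos = signal.butter(order, cutoff, btype="highpass", fs=sample_rate,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def extract_epochs(x, triggers, sample_rate=SAMPLE_RATE_HZ,
                   window_ms=EPOCH_WINDOW_MS):
    """Cut a continuous series into trigger-aligned epochs.

    Triggers whose window would fall off either end are dropped with a
    warning. Returns (epochs [n, len], time_ms, kept trigger indices).
    """
    x = np.asarray(x, dtype=float)
    lo = int(round(window_ms[0] / 1000.0 * sample_rate))
    hi = int(round(window_ms[1] / 1000.0 * sample_rate))
    rows, kept = [], []
    for i, trig in enumerate(np.asarray(triggers, dtype=int)):
        if trig + lo < 0 or trig + hi > x.size:
            warnings.warn(f"trigger {trig} too close to recording edge")
            continue
        rows.append(x[trig + lo:trig + hi])
        kept.append(i)
    time_ms = np.arange(lo, hi) / sample_rate * 1000.0
    return np.array(rows), time_ms, np.array(kept, dtype=int)


def reject_outliers(epochs, fraction=OUTLIER_FRACTION):
    """Discard epochs extreme in excursion or variability.

    The union of the top ``fraction`` (ceiling count) of epochs by
    peak-to-peak voltage excursion and by per-epoch SD is rejected. Ties
    break by epoch index, keeping earlier epochs.

    Returns (kept epochs, kept index array, report) where report lists
    {'epoch': i, 'rules': [...]} per rejected epoch.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2 or epochs.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 epochs")
    n = epochs.shape[0]
    k = math.ceil(fraction * n)
    excursion = np.ptp(epochs, axis=1)
    sd = epochs.std(axis=1)

    def top_k(metric):
        # Descending metric; ties resolved toward later epochs so that
        # earlier epochs are kept.
        order = np.lexsort((-np.arange(n), -metric))
        return set(order[:k])

    by_exc = top_k(excursion)
    by_sd = top_k(sd)
    rejected = sorted(by_exc | by_sd)
    report = [
        {"epoch": int(i),
         "rules": (["excursion"] if i in by_exc else [])
                  + (["sd"] if i in by_sd else [])}
        for i in rejected
    ]
    keep = np.array([i for i in range(n) if i not in set(rejected)], dtype=int)
    return epochs[keep], keep, report


def average_abr(epoch_set: ABREpochSet, *, window_ms=EPOCH_WINDOW_MS,
                outlier_fraction=OUTLIER_FRACTION,
                reject=True) -> ABRResult:
    """Average already-cleaned epochs with side-dependent polarity.

    Assumes cross-talk removal and filtering were applied to the
    continuous ``neural`` series (see :func:`preprocess_abr` for the
    full pipeline). Left-side responses are multiplied by -1 so Wave 1
    is expected positive for both sides.
    """
    epochs, time_ms, _ = extract_epochs(epoch_set.neural, epoch_set.triggers,
                                        epoch_set.sample_rate, window_ms)
    n_total = epochs.shape[0]
    if n_total == 0:
        raise ValueError("no complete epochs in recording")
    report = []
    if reject:
        epochs, _, report = reject_outliers(epochs, outlier_fraction)
    if epochs.shape[0] == 0:
        raise ValueError("all epochs rejected")
    waveform = epochs.mean(axis=0)
    invert = epoch_set.side == "left"
    if invert:
        waveform = -waveform
    return ABRResult(waveform=waveform, time_ms=time_ms,
                     n_epochs_kept=epochs.shape[0],
                     n_rejected=n_total - epochs.shape[0],
                     polarity_applied=invert, rejection_report=report)


def preprocess_abr(epoch_set: ABREpochSet, *, filter_len=FIR_TAPS,
                   cutoff=HIGHPASS_HZ, window_ms=EPOCH_WINDOW_MS,
                   outlier_fraction=OUTLIER_FRACTION) -> ABRResult:
    """Full pipeline: cross-talk removal, high-pass, rejection, averaging."""
    cleaned = remove_crosstalk(epoch_set.neural, epoch_set.speaker, filter_len)
    filtered = highpass(cleaned, cutoff, epoch_set.sample_rate)
    cleaned_set = ABREpochSet(
        neural=filtered, speaker=epoch_set.speaker,
        triggers=epoch_set.triggers, sample_rate=epoch_set.sample_rate,
        side=epoch_set.side, level_dba=epoch_set.level_dba,
    )
    return average_abr(cleaned_set, window_ms=window_ms,
                       outlier_fraction=outlier_fraction)


def write_result(path_csv, path_json, result: ABRResult):
    """Persist the averaged waveform (CSV) and rejection report (JSON)."""
    pd.DataFrame({"time_ms": result.time_ms,
                  "voltage_uv": result.waveform}).to_csv(path_csv, index=False)
    with open(path_json, "w") as fh:
        json.dump({"n_epochs_kept": result.n_epochs_kept,
                   "n_rejected": result.n_rejected,
                   "polarity_applied": result.polarity_applied,
                   "rejected": result.rejection_report}, fh, indent=2)
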