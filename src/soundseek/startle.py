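"""Acoustic startle quantification from keypoint tracks.

The startle reflex — a rapid whole-body contraction to a loud,
unexpected sound — is read out from video pose tracks: movement speed is
the per-frame distance moved by each tracked body part, averaged across
parts, and the startle magnitude is the mean speed over the first five
frames (167 ms at 30 frames/s) after stimulus onset. Startle-eliciting
bursts at 80 and 90 dB SPL evoke comparable responses and are pooled.
Units stay in px/frame; no physical-space calibration is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from soundseek.trajectory import PoseTrack

__all__ = ["StartleTrace", "movement_speed", "align_and_magnitude"]

STARTLE_WINDOW_FRAMES = 5


@dataclass(frozen=True)
class StartleTrace:
    """Speed trace around one stimulus onset.

    frames_rel gives each sample's frame offset from onset; magnitude is
    the mean speed over the first ``window`` post-onset frames
    (including the onset frame itself).
    """

    frames_rel: np.ndarray
    speed: np.ndarray
    level_db: float
    magnitude: float


def movement_speed(track: PoseTrack) -> np.ndarray:
    """Mean keypoint displacement per frame (px/frame).

    speed[t] is the Euclidean distance moved between frames t-1 and t,
    averaged over keypoints; keypoints missing in either frame are
    excluded from that frame's mean. speed[0] is 0 by convention (no
    preceding frame).
    """
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames")
    disp = np.diff(track.coords, axis=0)  # (frames-1, nodes, 2)
    dist = np.linalg.norm(disp, axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(dist, axis=1)
    mean = np.nan_to_num(mean, nan=0.0)
    return np.concatenate([[0.0], mean])


def align_and_magnitude(speed, onsets, levels=None, *,
                        window=STARTLE_WINDOW_FRAMES, pre_frames=15,
                        post_frames=30):
    """Cut speed traces around onsets and compute startle magnitudes.

    Parameters
    ----------
    speed : per-frame speed series (from movement_speed).
    onsets : stimulus onset frame indices.
    levels : per-onset stimulus level (dB SPL); levels are pooled in the
        session magnitude (80/90 dB responses are treated as one
        condition).
    window : frames averaged for the magnitude, starting at the onset
        frame (5 frames = 167 ms at 30 fps).

    Returns (traces, session_magnitude): a StartleTrace per usable onset
    and the mean magnitude across them. Onsets too close to the end of
    the track are skipped with a warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    speed = np.asarray(speed, dtype=float)
    onsets = np.asarray(onsets, dtype=int)
    if levels is None:
        levels = np.full(len(onsets), np.nan)
    traces = []
    for onset, level in zip(onsets, levels):
        if onset < 0 or onset >= len(speed):
            raise ValueError(f"onset {onset} outside track")
        if onset + window > len(speed):
            warnings.warn(f"onset {onset} too close to track end; skipped")
            continue
        lo = max(0, onset - pre_frames)
        hi = min(len(speed), onset + post_frames)
        traces.append(StartleTrace(
            frames_rel=np.arange(lo, hi) - onset,
            speed=speed[lo:hi],
            level_db=float(level),
            magnitude=float(speed[onset:onset + window].mean()),
        ))
    if not traces:
        raise ValueError("no usable onsets")
    session_magnitude = float(np.mean([t.magnitude for t in traces]))
    return traces, session_magnitude
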