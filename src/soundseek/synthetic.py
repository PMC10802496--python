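"""Seeded synthetic-data generators with known ground truth.

These generators stand in for the study's raw recordings so every
pipeline stage can be exercised end to end and scored exactly:

- :func:`gen_pose_session` renders agent trajectories from the task
  simulator into 30 fps keypoint tracks (camera-pixel frame, Gaussian
  keypoint jitter) plus the matching event log and ground-truth visit
  sequences.
- :func:`gen_startle_session` builds a startle-chamber track: reflected
  Brownian baseline wander plus, for hearing states that respond, a
  movement burst at each stimulus onset.
- :func:`gen_abr_recording` synthesizes a continuous ABR recording:
  a known evoked template at each click, speaker cross-talk through a
  known FIR filter, white sensor noise, and planted high-amplitude
  outlier epochs.

Identical seeds yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from soundseek.abr import ABREpochSet
from soundseek.arena import ArenaGeometry
from soundseek.task_sim import AgentPolicy, session_to_events, simulate_session
from soundseek.trajectory import PoseTrack

__all__ = [
    "SynthConfig",
    "KEYPOINT_NAMES",
    "gen_pose_session",
    "gen_startle_session",
    "gen_abr_recording",
]

#: Tracked body parts (snout leads; the rest trail along the path).
KEYPOINT_NAMES = [
    "snout", "head", "trunk",
    "forelimb_l", "forelimb_r", "hindlimb_l", "hindlimb_r",
    "tail_base",
]

FRAME_SIZE_PX = (640, 480)
FRAME_RATE = 30.0


@dataclass
class SynthConfig:
    """Knobs of the synthetic-data generators.

    px_per_cm / frame_center_px define the arena-cm -> camera-px affine;
    jitter_px is the Gaussian keypoint noise SD; speed_cm_s the
    locomotion speed; startle_profiles map hearing state to (response
    amplitude px/frame, latency frames); the abr_* fields shape the
    synthetic ABR recording.
    """

    seed: int = 0
    px_per_cm: float = 10.0
    frame_center_px: tuple = (320.0, 240.0)
    jitter_px: float = 2.0
    speed_cm_s: float = 15.0
    frame_rate: float = FRAME_RATE
    # hearing state -> (burst amplitude px/frame, latency frames)
    startle_profiles: dict = field(default_factory=lambda: {
        "intact": (12.0, 0),
        "sham": (12.0, 0),
        "unilateral": (10.0, 0),
        "bilateral": (0.0, 0),
    })
    baseline_step_px: float = 1.0
    abr_n_epochs: int = 750
    abr_trigger_spacing_s: float = 0.033
    abr_noise_uv: float = 2.0
    abr_template_uv: float = 5.0
    abr_outlier_fraction: float = 0.05
    abr_crosstalk_fir: np.ndarray = field(
        default_factory=lambda: np.array([0.8, -0.5, 0.3, -0.1, 0.05])
    )

    def __post_init__(self):
        if self.jitter_px < 0 or self.baseline_step_px < 0:
            raise ValueError("noise SDs must be >= 0")
        for state, (amp, lat) in self.startle_profiles.items():
            if amp < 0:
                raise ValueError(f"negative startle amplitude for {state}")
        if not 0.0 <= self.abr_outlier_fraction < 1.0:
            raise ValueError("abr_outlier_fraction must be in [0, 1)")


def _cm_to_px(xy_cm, config: SynthConfig):
    return np.asarray(xy_cm) * config.px_per_cm + np.asarray(
        config.frame_center_px
    )


def gen_pose_session(policy: AgentPolicy, arena: ArenaGeometry, n_trials,
                     config: SynthConfig | None = None, mode="fixed"):
    """Simulate a session and render it as a camera-frame pose track.

    The simulator's piecewise-linear waypoint trajectories are sampled
    at the video frame rate; the snout follows the path exactly (plus
    jitter) and the remaining keypoints trail behind it along the path
    at fixed arc-length offsets, emulating a body. Events keep the same
    clock as the video (time 0 = frame 0).

    Returns (track, events, records): the PoseTrack in px with the cm
    transform attached, the JSON-lines-ready event list, and the
    simulator's TrialRecords (ground truth).
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    records = simulate_session(policy, arena, n_trials, mode=mode, rng=rng,
                               speed=config.speed_cm_s)
    events = session_to_events(records)

    # Stitch all trials' waypoints into one (t, x, y) path.
    pts = [wp for rec in records for wp in rec.waypoints]
    t = np.array([p[0] for p in pts])
    xy = np.array([[p[1], p[2]] for p in pts])
    # Waypoint times are non-decreasing; collapse zero-length holds for interp.
    t_end = t[-1]
    n_frames = int(np.floor(t_end * config.frame_rate)) + 1
    ft = np.arange(n_frames) / config.frame_rate
    x = np.interp(ft, t, xy[:, 0])
    y = np.interp(ft, t, xy[:, 1])
    snout_cm = np.column_stack([x, y])

    # Trailing keypoints: positions a fixed arc length behind the snout.
    offsets_cm = {
        "snout": 0.0, "head": 1.0, "trunk": 3.0,
        "forelimb_l": 2.0, "forelimb_r": 2.0,
        "hindlimb_l": 4.5, "hindlimb_r": 4.5,
        "tail_base": 6.0,
    }
    seg = np.linalg.norm(np.diff(snout_cm, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    coords_cm = np.empty((n_frames, len(KEYPOINT_NAMES), 2))
    for j, name in enumerate(KEYPOINT_NAMES):
        lag = offsets_cm[name]
        target = np.maximum(arc - lag, 0.0)
        coords_cm[:, j, 0] = np.interp(target, arc, snout_cm[:, 0])
        coords_cm[:, j, 1] = np.interp(target, arc, snout_cm[:, 1])

    coords_px = coords_cm * config.px_per_cm + np.asarray(config.frame_center_px)
    coords_px += rng.normal(0.0, config.jitter_px, size=coords_px.shape)
    track = PoseTrack(
        coords=coords_px, node_names=list(KEYPOINT_NAMES),
        frame_rate=config.frame_rate,
        transform=(config.px_per_cm, np.asarray(config.frame_center_px)),
    )
    return track, events, records


def gen_startle_session(hearing_state, n_stimuli,
                        config: SynthConfig | None = None, *,
                        isi_range_s=(5.0, 30.0), window_frames=5):
    """Synthesize a startle-chamber pose track and stimulus onset list.

    Baseline movement is a reflected Brownian wander inside the chamber;
    responsive hearing states add a movement burst of the configured
    amplitude lasting ``window_frames`` frames at each onset (levels
    alternate 80/90 dB SPL, which downstream analysis pools). The
    bilateral profile produces no burst. Onsets are spaced uniformly
    within ``isi_range_s``.

    Returns (track, onset_frames, levels_db).
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    if isi_range_s[0] * FRAME_RATE <= window_frames:
        raise ValueError("inter-stimulus interval shorter than the "
                         "startle window")
    config = config or SynthConfig()
    if hearing_state not in config.startle_profiles:
        raise ValueError(f"unknown hearing state {hearing_state!r}")
    amp, latency = config.startle_profiles[hearing_state]
    rng = np.random.default_rng(config.seed)

    isis = rng.uniform(*isi_range_s, size=n_stimuli)
    onset_times = np.cumsum(isis)
    onsets = np.round(onset_times * config.frame_rate).astype(int)
    levels = np.where(np.arange(n_stimuli) % 2 == 0, 80.0, 90.0)
    n_frames = int(onsets[-1] + 5.0 * config.frame_rate)

    # Reflected Brownian baseline inside a chamber-sized pixel box.
    box = np.array([[40.0, 600.0], [40.0, 440.0]])
    steps = rng.normal(0.0, config.baseline_step_px, size=(n_frames, 2))
    # Startle bursts: directed displacement spikes after each onset.
    for onset in onsets:
        f0 = onset + latency
        direction = rng.standard_normal(2)
        direction /= np.linalg.norm(direction)
        steps[f0:f0 + window_frames] = amp * direction
    pos = np.empty((n_frames, 2))
    cur = np.array([320.0, 240.0])
    for f in range(n_frames):
        cur = cur + steps[f]
        # Reflect at walls.
        for d in range(2):
            lo, hi = box[d]
            if cur[d] < lo:
                cur[d] = 2 * lo - cur[d]
            elif cur[d] > hi:
                cur[d] = 2 * hi - cur[d]
        pos[f] = cur

    body_offsets = rng.uniform(-12.0, 12.0, size=(len(KEYPOINT_NAMES), 2))
    body_offsets[0] = 0.0
    coords = pos[:, None, :] + body_offsets[None, :, :]
    coords += rng.normal(0.0, config.jitter_px, size=coords.shape)
    track = PoseTrack(coords=coords, node_names=list(KEYPOINT_NAMES),
                      frame_rate=config.frame_rate)
    return track, onsets, levels


def _abr_template(sample_rate, amplitude_uv):
    """Wave-1-like evoked shape: damped oscillation from ~2 ms post-click.

    The onset latency (acoustic travel plus cochlear/neural delay) is
    kept beyond the cross-talk FIR span so the evoked response is not
    collinear with the lagged speaker signal — on the real rig the
    speaker-to-electrode bleed is electrical (instantaneous) while the
    evoked response arrives milliseconds later.
    """
    t = np.arange(int(0.006 * sample_rate)) / sample_rate  # 6 ms
    shape = np.sin(2 * np.pi * 900.0 * t) * np.exp(-t / 0.0015)
    delay = np.zeros(int(0.003 * sample_rate))
    template = np.concatenate([delay, shape])
    return amplitude_uv * template / np.abs(template).max()


def gen_abr_recording(config: SynthConfig | None = None, *, side="right",
                      level_dba=70.0, sample_rate=16_000):
    """Synthesize a continuous ABR recording with known ground truth.

    neural = evoked template at each trigger + FIR(speaker) cross-talk
    + white noise; a configured fraction of epochs is planted as
    outliers with 10x-amplitude noise. The speaker channel carries a
    biphasic 0.1 ms click at each trigger.

    Returns (ABREpochSet, info) with info holding the ground-truth
    template, crosstalk FIR, and planted outlier epoch indices.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    n_ep = config.abr_n_epochs
    spacing = int(round(config.abr_trigger_spacing_s * sample_rate))
    margin = int(0.005 * sample_rate)
    triggers = margin + spacing * np.arange(n_ep)
    n_samples = int(triggers[-1] + spacing)

    speaker = np.zeros(n_samples)
    click_len = max(1, int(round(0.0001 * sample_rate)))
    for trig in triggers:
        speaker[trig:trig + click_len] = 1.0
        speaker[trig + click_len:trig + 2 * click_len] = -1.0

    template = _abr_template(sample_rate, config.abr_template_uv)
    neural = np.zeros(n_samples)
    for trig in triggers:
        neural[trig:trig + template.size] += template[
            : max(0, min(template.size, n_samples - trig))
        ]
    neural += np.convolve(speaker, config.abr_crosstalk_fir)[:n_samples]
    neural += rng.normal(0.0, config.abr_noise_uv, size=n_samples)

    n_out = int(round(config.abr_outlier_fraction * n_ep))
    outlier_idx = np.sort(rng.choice(n_ep, size=n_out, replace=False))
    for i in outlier_idx:
        lo = triggers[i] - int(0.002 * sample_rate)
        hi = triggers[i] + int(0.010 * sample_rate)
        neural[max(lo, 0):hi] += rng.normal(
            0.0, 10.0 * max(config.abr_noise_uv, 1.0), size=hi - max(lo, 0)
        )

    epoch_set = ABREpochSet(neural=neural, speaker=speaker, triggers=triggers,
                            sample_rate=sample_rate, side=side,
                            level_dba=level_dba)
    info = {
        "template": template,
        "crosstalk_fir": np.asarray(config.abr_crosstalk_fir),
        "outlier_epochs": outlier_idx,
    }
    return epoch_set, info
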