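"""Chamber-entry detection and classification from pose tracks.

A chamber entry is the video frame on which the snout keypoint crosses
an internal divider, i.e. first lies inside a chamber polygon after
having been in the central region. Entries are classified per trial:

- *duplicate*: re-entry into a chamber already visited this trial;
- *cycling*: entry into a chamber ring-adjacent to the one just exited
  (the first entry of a trial is never cycling);
- *with poke* vs *without poke* (a "check"): whether the visit
  culminated in a poke of that chamber's port. Metrics discard duplicate
  entries and entries into the previous goal before the with/without
  split, so kept entries satisfy n_with_poke + n_without_poke.

The chance level for kept entries under a random-order search of the
8-chamber arena is 4 per trial (the goal's rank is uniform on 1..7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from soundseek.arena import ArenaGeometry

__all__ = [
    "PoseTrack",
    "ChamberEntry",
    "EntryMetrics",
    "detect_entries",
    "classify_entries",
    "entries_chance_level",
    "read_pose_hdf5",
    "write_pose_hdf5",
    "read_pose_csv",
    "write_pose_csv",
]

#: Frames the snout must spend back in the center before a chamber visit
#: counts as exited (100 ms at 30 fps); quicker re-crossings merge.
DEBOUNCE_FRAMES = 3
#: Longest gap of missing snout samples bridged by linear interpolation.
MAX_INTERP_FRAMES = 5


@dataclass
class PoseTrack:
    """Keypoint time series.

    coords has shape (n_frames, n_nodes, 2) with NaN for missing
    samples. Positions may be in camera px or arena cm; ``transform``
    (a, b) maps px to cm as ``cm = (px - b) / a`` when given.
    """

    coords: np.ndarray
    node_names: list
    frame_rate: float = 30.0
    transform: tuple | None = None  # (scale px/cm, offset px (2,))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (frames, nodes, 2)")
        if self.coords.shape[1] != len(self.node_names):
            raise ValueError("node_names length must match coords")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self):
        return self.coords.shape[0]

    def node(self, name):
        try:
            return self.coords[:, self.node_names.index(name), :]
        except ValueError:
            raise KeyError(f"no keypoint named {name!r}") from None

    def to_cm(self, xy_px):
        if self.transform is None:
            return xy_px
        scale, offset = self.transform
        return (xy_px - np.asarray(offset)) / scale


@dataclass(frozen=True)
class ChamberEntry:
    trial: int
    frame: int
    chamber: int
    exit_frame: int | None = None
    is_duplicate: bool = False
    is_cycling: bool = False
    is_prev_goal: bool = False
    with_poke: bool = False
    is_check: bool = False


@dataclass(frozen=True)
class EntryMetrics:
    """Per-trial entry counts after the exclusion rules."""

    trial: int
    n_duplicate: int
    n_cycling: int
    n_entries_kept: int
    n_with_poke: int
    n_without_poke: int

    def __post_init__(self):
        if self.n_entries_kept != self.n_with_poke + self.n_without_poke:
            raise ValueError("kept entries must split into with/without poke")


def _interpolate_gaps(xy, max_gap):
    """Linearly bridge NaN runs of length <= max_gap; longer runs stay NaN."""
    xy = xy.copy()
    bad = np.isnan(xy).any(axis=1)
    if not bad.any():
        return xy
    idx = np.arange(len(xy))
    # Identify runs of missing frames.
    edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]
    good = ~bad
    for s, e in zip(starts, ends):
        if e - s <= max_gap and s > 0 and e < len(xy) and good[s - 1] and good[e]:
            for d in range(2):
                xy[s:e, d] = np.interp(idx[s:e], [s - 1, e], [xy[s - 1, d], xy[e, d]])
    return xy


def detect_entries(track: PoseTrack, arena: ArenaGeometry, *, trial=0,
                   debounce=DEBOUNCE_FRAMES,
                   max_interp=MAX_INTERP_FRAMES) -> list[ChamberEntry]:
    """Detect chamber entries from the snout trajectory.

    An entry fires at the first frame the snout lies inside a chamber
    after having been in the central region; the visit ends once the
    snout has been back in the center for ``debounce`` consecutive
    frames. Re-crossing into the same chamber before that merges with
    the ongoing visit. Frames outside every region (wall overshoot,
    unbridged gaps) hold the previous state.
    """
    snout = track.to_cm(track.node("snout"))
    if np.isnan(snout).all():
        raise ValueError("snout keypoint entirely missing")
    n_missing = int(np.isnan(snout).any(axis=1).sum())
    snout = _interpolate_gaps(snout, max_interp)
    if np.isnan(snout).any(axis=1).sum() > 0 and n_missing:
        warnings.warn("gaps longer than the interpolation window remain; "
                      "frames treated as unlocated")
    region = arena.locate(snout)

    entries = []
    current = None          # chamber id of ongoing visit
    entry_frame = None
    center_run = 0          # consecutive center frames since leaving chamber
    pending_exit = None     # frame the snout last left the chamber
    for f, r in enumerate(region):
        if current is None:
            if r >= 0:
                current, entry_frame, center_run = int(r), f, 0
                pending_exit = None
        else:
            if r == current:
                center_run, pending_exit = 0, None
            elif r == -1:
                if pending_exit is None:
                    pending_exit = f
                center_run += 1
                if center_run >= debounce:
                    entries.append(ChamberEntry(trial=trial, frame=entry_frame,
                                                chamber=current,
                                                exit_frame=pending_exit))
                    current, pending_exit, center_run = None, None, 0
            elif r >= 0:
                # Jumped to a different chamber (corner cut): close the
                # old visit and open a new one.
                entries.append(ChamberEntry(trial=trial, frame=entry_frame,
                                            chamber=current,
                                            exit_frame=pending_exit or f))
                current, entry_frame, center_run = int(r), f, 0
                pending_exit = None
            # r == -2/-3: unlocated, hold state.
    if current is not None:
        entries.append(ChamberEntry(trial=trial, frame=entry_frame,
                                    chamber=current, exit_frame=None))
    return entries


def classify_entries(entries, pokes, goal, prev_goal, *,
                     n_ports=8, frame_rate=30.0, trial_end_frame=None,
                     attribute_poke_to_first=True):
    """Flag entries and compute per-trial entry metrics.

    Parameters
    ----------
    entries : ordered ChamberEntry list for one trial.
    pokes : (time_s, port) pairs on the same clock as entry frames
        (time 0 = frame 0).
    goal, prev_goal : trial's goal port and the previous goal (None on a
        session's first trial).
    attribute_poke_to_first : when a poke happens during a duplicate
        (discarded) visit, credit the kept first entry of that chamber
        as with-poke, honoring the "eventually culminated in a poke"
        reading. Set False to attribute strictly to the visit containing
        the poke.

    Returns (flagged entries, EntryMetrics).
    """
    entries = list(entries)
    trial_id = entries[0].trial if entries else 0
    poke_frames = [(int(round(t * frame_rate)), port) for t, port in pokes]

    # Visit windows: entry frame to next entry frame (or trial end).
    windows = []
    for i, e in enumerate(entries):
        end = entries[i + 1].frame if i + 1 < len(entries) else trial_end_frame
        windows.append((e.frame, end))

    entered = {e.chamber for e in entries}
    for f, port in poke_frames:
        if port not in entered:
            warnings.warn(f"poke into port {port} with no detected entry")

    flagged = []
    seen = set()
    prev_exited = None
    poked_in_visit = []
    for (e, (w0, w1)) in zip(entries, windows):
        with_poke = any(
            port == e.chamber and w0 <= f and (w1 is None or f < w1)
            for f, port in poke_frames
        )
        poked_in_visit.append(with_poke)
        is_dup = e.chamber in seen
        seen.add(e.chamber)
        is_cyc = prev_exited is not None and e.chamber in (
            (prev_exited + 1) % n_ports, (prev_exited - 1) % n_ports
        )
        prev_exited = e.chamber
        flagged.append((e, is_dup, is_cyc, with_poke))

    if attribute_poke_to_first:
        # Kept first entry inherits pokes made on later duplicate visits.
        chamber_poked = {}
        for (e, _, _, wp) in flagged:
            chamber_poked[e.chamber] = chamber_poked.get(e.chamber, False) or wp
    else:
        chamber_poked = None

    out = []
    n_dup = n_cyc = n_kept = n_with = n_without = 0
    for (e, is_dup, is_cyc, wp) in flagged:
        is_prev = prev_goal is not None and e.chamber == prev_goal
        if chamber_poked is not None and not is_dup:
            wp = chamber_poked[e.chamber]
        kept = not is_dup and not is_prev
        is_check = kept and not wp
        out.append(ChamberEntry(
            trial=e.trial, frame=e.frame, chamber=e.chamber,
            exit_frame=e.exit_frame, is_duplicate=is_dup, is_cycling=is_cyc,
            is_prev_goal=is_prev, with_poke=wp, is_check=is_check,
        ))
        n_dup += is_dup
        n_cyc += is_cyc
        if kept:
            n_kept += 1
            n_with += wp
            n_without += not wp
    metrics = EntryMetrics(trial=trial_id, n_duplicate=n_dup, n_cycling=n_cyc,
                           n_entries_kept=n_kept, n_with_poke=n_with,
                           n_without_poke=n_without)
    return out, metrics


def entries_chance_level(arena: ArenaGeometry, n=100_000, rng=0,
                         method="exact"):
    """Expected kept entries per trial for a random-order searcher.

    With one chamber excluded (the previous goal), the goal's rank in a
    uniformly random visit order is uniform on 1..n_ports-1, so the
    exact expectation is n_ports/2 (4 for the octagonal arena).
    ``method='mc'`` estimates the same quantity by simulation.
    """
    m = arena.n_ports - 1  # eligible chambers
    if method == "exact":
        return float(np.mean(np.arange(1, m + 1)))
    rng = np.random.default_rng(rng)
    ranks = rng.integers(1, m + 1, size=n)
    return float(ranks.mean())


# ---------------------------------------------------------------------------
# Pose-track I/O: SLEAP-analysis HDF5 dialect and a flat CSV dialect
# ---------------------------------------------------------------------------

def read_pose_hdf5(path, frame_rate=30.0) -> PoseTrack:
    """Read a SLEAP-analysis-style HDF5 file.

    Expects datasets ``tracks`` with shape (1, 2, nodes, frames) or
    (frames, nodes, 2), and ``node_names``. An optional ``transform``
    dataset [scale, bx, by] maps px to cm.
    """
    with h5py.File(path, "r") as fh:
        tracks = fh["tracks"][()]
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in fh["node_names"][()]]
        transform = None
        if "transform" in fh:
            t = fh["transform"][()]
            transform = (float(t[0]), np.array(t[1:3]))
        if "frame_rate" in fh.attrs:
            frame_rate = float(fh.attrs["frame_rate"])
    if tracks.ndim == 4:  # SLEAP layout (tracks, xy, nodes, frames)
        coords = np.transpose(tracks[0], (2, 1, 0))
    else:
        coords = tracks
    return PoseTrack(coords=coords, node_names=names, frame_rate=frame_rate,
                     transform=transform)


def write_pose_hdf5(path, track: PoseTrack):
    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "tracks",
            data=np.transpose(track.coords, (2, 1, 0))[None, ...],
        )
        fh.create_dataset(
            "node_names",
            data=np.array([n.encode() for n in track.node_names]),
        )
        if track.transform is not None:
            scale, offset = track.transform
            fh.create_dataset("transform",
                              data=np.array([scale, offset[0], offset[1]]))
        fh.attrs["frame_rate"] = track.frame_rate


def write_pose_csv(path, track: PoseTrack):
    """Flat CSV dialect: columns frame, node, x, y (NaN for missing)."""
    frames, nodes = track.coords.shape[:2]
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(frames), nodes),
        "node": np.tile(track.node_names, frames),
        "x": track.coords[:, :, 0].ravel(),
        "y": track.coords[:, :, 1].ravel(),
    })
    df.to_csv(path, index=False)


def read_pose_csv(path, frame_rate=30.0, transform=None) -> PoseTrack:
    df = pd.read_csv(path)
    names = list(dict.fromkeys(df["node"]))
    n_frames = int(df["frame"].max()) + 1
    coords = np.full((n_frames, len(names), 2), np.nan)
    node_idx = {n: i for i, n in enumerate(names)}
    coords[df["frame"].to_numpy(),
           df["node"].map(node_idx).to_numpy()] = df[["x", "y"]].to_numpy()
    return PoseTrack(coords=coords, node_names=names, frame_rate=frame_rate,
                     transform=transform)


def analyze_session(track: PoseTrack, events, arena: ArenaGeometry, *,
                    debounce=DEBOUNCE_FRAMES, max_interp=MAX_INTERP_FRAMES,
                    attribute_poke_to_first=True):
    """Full pose pipeline for a session: detect, window, classify.

    Entries are detected once over the whole track, then assigned to
    trials by the event log's trial windows (trial start to reward);
    entries outside any window — e.g. during the inter-trial delay —
    are dropped. Each trial's entries are then classified against its
    pokes, goal and previous goal.

    Parameters
    ----------
    track : session-long PoseTrack (same clock as the event log;
        time 0 = frame 0).
    events : event list in the simulator/rig dialect (needs trial_start
        with goal/prev_goal, poke, reward).
    arena : ArenaGeometry in the cm frame of ``track.transform``.

    Returns (per-trial entry lists, per-trial EntryMetrics list).
    """
    from soundseek.task_sim import events_to_records

    fps = track.frame_rate
    all_entries = detect_entries(track, arena, debounce=debounce,
                                 max_interp=max_interp)
    trials = events_to_records(events)
    starts = {}
    for ev in events:
        if ev["type"] == "trial_start":
            starts[ev["trial"]] = ev["t"]

    per_trial_entries, per_trial_metrics = [], []
    for tr in trials:
        tid = tr["trial"]
        if tr["reward_time"] is None or tid not in starts:
            continue
        f_lo = int(np.floor(starts[tid] * fps))
        f_hi = int(np.round(tr["reward_time"] * fps)) + 1
        sel = [ChamberEntry(trial=tid, frame=e.frame, chamber=e.chamber,
                            exit_frame=e.exit_frame)
               for e in all_entries if f_lo <= e.frame < f_hi]
        flagged, metrics = classify_entries(
            sel, tr["pokes"], tr["goal"], tr["prev_goal"],
            n_ports=arena.n_ports, frame_rate=fps, trial_end_frame=f_hi,
            attribute_poke_to_first=attribute_poke_to_first)
        per_trial_entries.append(flagged)
        per_trial_metrics.append(metrics)
    return per_trial_entries, per_trial_metrics


def metrics_to_frame(metrics_list) -> pd.DataFrame:
    """Stack per-trial EntryMetrics into a DataFrame (CSV-ready)."""
    return pd.DataFrame([m.__dict__ for m in metrics_list])
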