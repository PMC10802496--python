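"""Agent-based simulation of the eight-chamber sound-seeking task.

On each trial one port (the goal, below the active speaker) is chosen at
random, never repeating the previous trial's goal. The trial lasts until
the agent pokes the goal port. Four stationary search policies are
provided:

- ``random``: visits distinct eligible ports (previous goal excluded) in
  uniformly random order, poking each, until the goal.
- ``cycling``: walks the ring of chambers in one direction from a start
  port, poking each port in turn (the "traplining" strategy).
- ``direct``: goes straight to the goal (an idealized expert).
- ``checker``: enters chambers in ring order and pokes a chamber's port
  only when it detects sound there (Bernoulli, probability set by sound
  level and hearing state); after a configurable number of silent laps it
  falls back to poking every port in ring order, which guarantees
  termination even when nothing is ever detected.

Each chamber visit also yields a waypoint path
(center -> entryway -> port -> entryway -> center) used by the
synthetic-pose generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soundseek.arena import ArenaGeometry
from soundseek.stimulus import StimulusParams, sample_trial_params

__all__ = [
    "AgentPolicy",
    "TrialRecord",
    "select_goal",
    "run_trial",
    "simulate_session",
    "events_to_records",
    "session_to_events",
    "write_events_jsonl",
    "read_events_jsonl",
]

#: Locomotion speed for waypoint timing (cm/s); the rig never measures
#: speed, so this is a synthesis convention only.
DEFAULT_SPEED_CM_S = 15.0
POKE_DWELL_S = 0.5
INTER_TRIAL_S = 1.0


@dataclass(frozen=True)
class AgentPolicy:
    """A stationary search policy.

    kind : 'random' | 'cycling' | 'direct' | 'checker'
    detect_prob : float or callable(level_db, ear_state) -> [0, 1]
        Probability the checker detects the goal sound while inside the
        goal chamber.
    ear_state : 'intact' | 'unilateral_left' | 'unilateral_right' | 'bilateral'
    false_alarm : probability the checker pokes a silent chamber's port.
    direction : +1 (counterclockwise) or -1, for cycling/checker.
    start : fixed start chamber for cycling/checker, or None for a
        uniformly random start each trial.
    max_laps : silent laps before the checker's poke-everything fallback.
    """

    kind: str = "random"
    detect_prob: object = 0.9
    ear_state: str = "intact"
    false_alarm: float = 0.0
    direction: int = 1
    start: int | None = None
    max_laps: int = 2

    def __post_init__(self):
        if self.kind not in ("random", "cycling", "direct", "checker"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0.0 <= self.false_alarm <= 1.0:
            raise ValueError("false_alarm must be in [0, 1]")
        if isinstance(self.detect_prob, (int, float)) and not (
            0.0 <= self.detect_prob <= 1.0
        ):
            raise ValueError("detect_prob must be in [0, 1]")

    def p_detect(self, level_db: float) -> float:
        if callable(self.detect_prob):
            p = float(self.detect_prob(level_db, self.ear_state))
        else:
            p = float(self.detect_prob)
        if not 0.0 <= p <= 1.0:
            raise ValueError("detect_prob returned a value outside [0, 1]")
        return p


@dataclass
class TrialRecord:
    """One simulated trial: goal, events, and the ground-truth path."""

    index: int
    goal: int
    prev_goal: int | None
    stim: StimulusParams
    pokes: list = field(default_factory=list)    # (t, port)
    entries: list = field(default_factory=list)  # (t, chamber)
    reward_time: float = 0.0
    waypoints: list = field(default_factory=list)  # (t, x_cm, y_cm)
    start_time: float = 0.0

    def __post_init__(self):
        if self.pokes and self.pokes[-1][1] != self.goal:
            raise ValueError("last poke must be into the goal port")


def select_goal(prev_goal, n_ports, rng):
    """Choose the next goal uniformly, excluding the previous goal.

    With ``prev_goal=None`` (first trial) all ports are eligible.
    """
    if n_ports < 2:
        raise ValueError("need at least 2 ports")
    rng = np.random.default_rng(rng)
    if prev_goal is None:
        return int(rng.integers(n_ports))
    eligible = [p for p in range(n_ports) if p != prev_goal]
    return int(eligible[rng.integers(n_ports - 1)])


def _visit_plan(policy, goal, prev_goal, n_ports, level_db, rng):
    """Ordered (chamber, pokes_here) visit plan ending with a goal poke."""
    if policy.kind == "direct":
        return [(goal, True)]

    if policy.kind == "random":
        eligible = [p for p in range(n_ports) if p != prev_goal]
        order = list(rng.permutation(eligible))
        stop = order.index(goal)
        return [(int(c), True) for c in order[: stop + 1]]

    if policy.kind == "cycling":
        start = policy.start if policy.start is not None else int(rng.integers(n_ports))
        plan = []
        c = start
        while True:
            plan.append((c, True))
            if c == goal:
                return plan
            c = (c + policy.direction) % n_ports

    # checker
    p_detect = policy.p_detect(level_db)
    start = policy.start if policy.start is not None else int(rng.integers(n_ports))
    plan = []
    c = start
    for _ in range(policy.max_laps * n_ports):
        if c == goal:
            if rng.random() < p_detect:
                plan.append((c, True))
                return plan
            plan.append((c, False))
        else:
            if policy.false_alarm > 0 and rng.random() < policy.false_alarm:
                plan.append((c, True))
            else:
                plan.append((c, False))
        c = (c + policy.direction) % n_ports
    # Fallback: poke every port in ring order until the goal rewards.
    while True:
        plan.append((c, True))
        if c == goal:
            return plan
        c = (c + policy.direction) % n_ports


def run_trial(policy: AgentPolicy, arena: ArenaGeometry, goal, prev_goal,
              rng, *, index=0, stim=None, start_time=0.0,
              speed=DEFAULT_SPEED_CM_S) -> TrialRecord:
    """Simulate one trial; returns pokes, entries and waypoint trajectory.

    The agent starts at the arena center; each chamber visit is a
    constant-speed waypoint excursion center -> entryway -> port ->
    entryway -> center, with a dwell at the port when it pokes.
    """
    if goal == prev_goal:
        raise ValueError("goal must differ from prev_goal")
    if not 0 <= goal < arena.n_ports:
        raise ValueError(f"unknown port {goal}")
    rng = np.random.default_rng(rng)
    stim = stim or StimulusParams()
    plan = _visit_plan(policy, goal, prev_goal, arena.n_ports, stim.level, rng)

    rec = TrialRecord(index=index, goal=goal, prev_goal=prev_goal, stim=stim,
                      start_time=start_time)
    center = np.zeros(2)
    t = start_time
    pos = center.copy()
    rec.waypoints.append((t, pos[0], pos[1]))

    def goto(target):
        nonlocal t, pos
        dist = float(np.linalg.norm(target - pos))
        t += dist / speed
        pos = np.asarray(target, dtype=float).copy()
        rec.waypoints.append((t, pos[0], pos[1]))

    for chamber, pokes_here in plan:
        entry = arena.entry_point(chamber)
        port = arena.port_positions[chamber] * 0.97  # just inside the wall
        goto(entry)
        rec.entries.append((t, int(chamber)))
        goto(port)
        if pokes_here:
            rec.pokes.append((t, int(chamber)))
            t += POKE_DWELL_S
            rec.waypoints.append((t, pos[0], pos[1]))
        goto(entry)
        goto(center)

    rec.reward_time = rec.pokes[-1][0]
    return rec


def simulate_session(policy: AgentPolicy, arena: ArenaGeometry, n_trials,
                     mode="fixed", rng=0, speed=DEFAULT_SPEED_CM_S):
    """Simulate a session of sequential trials.

    Each trial's previous goal is the preceding trial's goal (the first
    trial has none); stimulus parameters follow ``mode``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng)
    records = []
    prev_goal = None
    t = 0.0
    for i in range(n_trials):
        goal = select_goal(prev_goal, arena.n_ports, rng)
        stim = sample_trial_params(mode, rng)
        rec = run_trial(policy, arena, goal, prev_goal, rng, index=i,
                        stim=stim, start_time=t, speed=speed)
        records.append(rec)
        # Next trial begins after the inter-trial delay, but never before
        # the agent has finished walking back to the center.
        t = max(rec.reward_time + INTER_TRIAL_S, rec.waypoints[-1][0])
        prev_goal = goal
    return records


# ---------------------------------------------------------------------------
# Event-log serialization (JSON-lines / CSV)
# ---------------------------------------------------------------------------

def session_to_events(records) -> list[dict]:
    """Flatten trial records into an ordered event list.

    Events are dicts {t, type, trial, port|chamber, goal, prev_goal};
    types are trial_start, entry, poke, reward.
    """
    events = []
    for rec in records:
        events.append({"t": rec.start_time, "type": "trial_start",
                       "trial": rec.index, "goal": rec.goal,
                       "prev_goal": rec.prev_goal})
        for t, chamber in rec.entries:
            events.append({"t": t, "type": "entry", "trial": rec.index,
                           "chamber": chamber})
        for t, port in rec.pokes:
            events.append({"t": t, "type": "poke", "trial": rec.index,
                           "port": port})
        events.append({"t": rec.reward_time, "type": "reward",
                       "trial": rec.index, "port": rec.goal})
    events.sort(key=lambda e: (e["trial"], e["t"], e["type"] == "reward"))
    return events


def events_to_records(events):
    """Group an event list back into per-trial poke/entry sequences.

    Returns a list of dicts with keys trial, goal, prev_goal, pokes
    [(t, port)], entries [(t, chamber)], reward_time. Works on logs from
    the simulator or real rigs using the same dialect.
    """
    trials = {}
    for ev in events:
        tr = trials.setdefault(ev["trial"], {"trial": ev["trial"],
                                             "goal": None, "prev_goal": None,
                                             "pokes": [], "entries": [],
                                             "reward_time": None})
        if ev["type"] == "trial_start":
            tr["goal"] = ev.get("goal")
            tr["prev_goal"] = ev.get("prev_goal")
        elif ev["type"] == "poke":
            tr["pokes"].append((ev["t"], ev["port"]))
        elif ev["type"] == "entry":
            tr["entries"].append((ev["t"], ev["chamber"]))
        elif ev["type"] == "reward":
            tr["reward_time"] = ev["t"]
            if tr["goal"] is None:
                tr["goal"] = ev.get("port")
    return [trials[k] for k in sorted(trials)]


def write_events_jsonl(path, events):
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev) + "\n")


def read_events_jsonl(path):
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def events_to_csv(path, events):
    pd.DataFrame(events).to_csv(path, index=False)


def events_from_csv(path):
    df = pd.read_csv(path)
    events = []
    for row in df.to_dict("records"):
        ev = {k: v for k, v in row.items() if pd.notna(v)}
        for key in ("trial", "port", "chamber", "goal", "prev_goal"):
            if key in ev:
                ev[key] = int(ev[key])
        events.append(ev)
    return events
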