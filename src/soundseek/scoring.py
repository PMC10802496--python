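"""Trial and session scoring for the sound-seeking task.

Two behavioral metrics are computed per trial. Pokes into the previously
rewarded port are disregarded entirely (it can never be the current
goal, and animals often perseverate there after reward):

- ``correct``: the first non-disregarded poke is into the goal.
- ``ports_poked``: the number of *distinct* ports poked up to and
  including the first goal poke, after disregarding the previous goal.
  Ranges from 1 (correct) to 7 (every eligible port). Chance level for
  a random searcher is 4 ports and fraction correct 1/7 ~ 0.143;
  perfect performance is 1 port and fraction correct 1.0.

The learning criterion splits sessions into "early" and "late" epochs at
the first session with mean ports poked strictly better than (below) 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialScore",
    "SessionSummary",
    "PORTS_POKED_CRITERION",
    "score_trial",
    "summarize_session",
    "learning_criterion",
    "performance_by_param",
]

PORTS_POKED_CRITERION = 2.5


@dataclass(frozen=True)
class TrialScore:
    """Outcome of one trial.

    ``first_trial`` marks scores computed without a previous-goal
    exclusion (session-opening trials); these can reach 8 ports and are
    excluded from session means by default.
    """

    correct: bool
    ports_poked: int
    first_trial: bool = False

    def __post_init__(self):
        if self.correct != (self.ports_poked == 1):
            raise ValueError("correct must hold exactly when ports_poked == 1")
        limit = 8 if self.first_trial else 7
        if not 1 <= self.ports_poked <= limit:
            raise ValueError(f"ports_poked {self.ports_poked} out of range")


@dataclass(frozen=True)
class SessionSummary:
    n_trials: int
    fraction_correct: float
    mean_ports_poked: float

    def __post_init__(self):
        if not 0.0 <= self.fraction_correct <= 1.0:
            raise ValueError("fraction_correct out of [0, 1]")
        if not 1.0 <= self.mean_ports_poked <= 7.0:
            raise ValueError("mean_ports_poked out of [1, 7]")


def score_trial(pokes, goal, prev_goal) -> TrialScore:
    """Score a trial from its ordered poke sequence.

    Parameters
    ----------
    pokes : sequence of port ids (or (t, port) pairs), ending at the goal.
    goal : rewarded port this trial.
    prev_goal : previous trial's goal, or None for a session's first
        trial (no exclusion applies; the score is flagged).

    Pokes into ``prev_goal`` are dropped, then ports_poked is the number
    of distinct ports up to and including the first goal poke; pokes
    after that are ignored (the trial ended at reward).
    """
    ports = [p[1] if isinstance(p, (tuple, list)) else p for p in pokes]
    if goal not in ports:
        raise ValueError("malformed trial: goal never poked")
    if prev_goal is not None and goal == prev_goal:
        raise ValueError("goal cannot equal prev_goal")
    filtered = [p for p in ports if p != prev_goal]
    upto = filtered[: filtered.index(goal) + 1]
    distinct = len(set(upto))
    return TrialScore(correct=(upto[0] == goal), ports_poked=distinct,
                      first_trial=prev_goal is None)


def summarize_session(scores, include_first_trial=False) -> SessionSummary:
    """Session means of the two metrics.

    First-trial scores (no previous-goal exclusion) are dropped by
    default so mean_ports_poked keeps its [1, 7] range.
    """
    kept = [s for s in scores if include_first_trial or not s.first_trial]
    if not kept:
        raise ValueError("no scorable trials in session")
    return SessionSummary(
        n_trials=len(kept),
        fraction_correct=float(np.mean([s.correct for s in kept])),
        mean_ports_poked=float(np.mean([s.ports_poked for s in kept])),
    )


def learning_criterion(summaries, threshold=PORTS_POKED_CRITERION):
    """First session beating the ports-poked criterion, plus epoch labels.

    Returns ``(index, labels)`` where index is the first session with
    mean_ports_poked strictly below ``threshold`` (performing *better
    than* 2.5 ports), or None if no session qualifies. Labels are
    'early' for sessions strictly before the criterion session and
    'late' from it onward ('early' everywhere if never met).
    """
    if not summaries:
        raise ValueError("need at least one session")
    means = [s.mean_ports_poked for s in summaries]
    idx = next((i for i, m in enumerate(means) if m < threshold), None)
    if idx is None:
        return None, ["early"] * len(means)
    return idx, ["early" if i < idx else "late" for i in range(len(means))]


#: Parameters binned/correlated on a log axis; level stays linear in dB.
_LOG_PARAMS = {"center_freq", "rate", "irregularity"}


def performance_by_param(trials, param, n_bins=5):
    """Ports poked as a function of one acoustic parameter.

    Parameters
    ----------
    trials : sequence of (StimulusParams, TrialScore) pairs from
        variable-mode sessions.
    param : 'center_freq' | 'level' | 'rate' | 'irregularity'
    n_bins : log-spaced bins (dB-spaced for level).

    Returns a dict with the binned means (DataFrame: bin_center, n,
    mean_ports_poked) and Pearson r / p of the (log-)parameter against
    ports poked.
    """
    values = np.array([getattr(stim, param) for stim, _ in trials], float)
    ports = np.array([score.ports_poked for _, score in trials], float)
    if values.size < 3:
        raise ValueError("need at least 3 trials")
    if np.ptp(values) == 0:
        raise ValueError(
            f"parameter {param!r} is constant (fixed-mode trials?)"
        )
    x = np.log(values) if param in _LOG_PARAMS else values
    r, p = stats.pearsonr(x, ports)

    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    which = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        center = (edges[b] + edges[b + 1]) / 2.0
        if param in _LOG_PARAMS:
            center = float(np.exp(center))
        rows.append({"bin_center": center, "n": int(mask.sum()),
                     "mean_ports_poked": float(ports[mask].mean())
                     if mask.any() else np.nan})
    return {"bins": pd.DataFrame(rows), "pearson_r": float(r),
            "p_value": float(p)}


def score_session_events(trial_dicts, include_first_trial=False):
    """Score an event-log session (output of events_to_records).

    Returns (list of TrialScore, SessionSummary).
    """
    scores = [
        score_trial(tr["pokes"], tr["goal"], tr["prev_goal"])
        for tr in trial_dicts
    ]
    return scores, summarize_session(scores,
                                     include_first_trial=include_first_trial)
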