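"""Simulate sound-seeking sessions and score them.

A random searcher defines chance performance (fraction correct 1/7 ~
0.143, mean 4 distinct ports poked per trial); a direct searcher defines
perfect performance (1.0 and 1). The learning criterion splits sessions
at the first one better than 2.5 ports poked.
"""

from soundseek.arena import ArenaGeometry
from soundseek.scoring import (learning_criterion, score_trial,
                               summarize_session)
from soundseek.task_sim import AgentPolicy, simulate_session

arena = ArenaGeometry.default()

for kind in ("random", "direct"):
    records = simulate_session(AgentPolicy(kind=kind), arena, 1000, rng=0)
    scores = [score_trial(r.pokes, r.goal, r.prev_goal) for r in records]
    s = summarize_session(scores)
    print(f"{kind:>7}: fraction correct {s.fraction_correct:.3f}, "
          f"ports poked {s.mean_ports_poked:.2f}")

# A toy learning trajectory: checker detection improving over sessions.
summaries = []
for session, p in enumerate([0.1, 0.3, 0.5, 0.8, 0.95]):
    policy = AgentPolicy(kind="checker", detect_prob=p)
    records = simulate_session(policy, arena, 200, rng=session)
    scores = [score_trial(r.pokes, r.goal, r.prev_goal) for r in records]
    summaries.append(summarize_session(scores))
idx, labels = learning_criterion(summaries)
means = [f"{s.mean_ports_poked:.2f}" for s in summaries]
print(f"session means {means} -> criterion at session {idx}, epochs {labels}")
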