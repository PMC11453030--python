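"""Simulate one stop-signal session and inspect the SSD staircases.

Runs the default session (30 practice go trials, then 3 blocks of 15
four-trial sets) for a horse-race participant and prints the staircase
levels and the medium-SSD stopping rate.
"""

import numpy as np

from gcsr import ParticipantModel, SessionConfig, SsdClass, TrialType, simulate_session

participant = ParticipantModel(go_rt_mean_ms=450, go_rt_sd_ms=100, ssrt_ms=200)
result = simulate_session(participant, SessionConfig(), seed=1)

trials = result.trials
print(f"simulated {len(trials)} trials "
      f"({sum(t.block == 0 for t in trials)} practice go trials)")

trace = result.staircase_trace
for block in (1, 2, 3):
    rows = trace[trace.block == block]
    print(f"block {block}: short {rows.short_ms.iloc[0]} ms, "
          f"medium {rows.medium_ms.iloc[0]} -> {rows.medium_ms.iloc[-1]} ms, "
          f"long {rows.long_ms.iloc[0]} ms")

medium = [t for t in trials if t.trial_type is TrialType.STOP
          and t.ssd_class is SsdClass.MEDIUM]
rate = np.mean([t.correct for t in medium])
print(f"medium-SSD stopping success: {rate:.0%} "
      "(the one-up/one-down staircase tracks 50%)")

sep = np.minimum(trace.medium_ms - trace.short_ms,
                 trace.long_ms - trace.medium_ms)
print(f"minimum staircase separation: {sep.min()} ms (never below 50 ms)")
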