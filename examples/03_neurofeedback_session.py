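"""Run a full synthetic neurofeedback session through the pipeline.

Eight trials (aL/aR alternating) stream scan-by-scan through the causal
cleaner; at each trial's end both models are inverted on the 90-scan
window and a feedback event is emitted: the display word (UP for aL,
DOWN for aR), the rounded log Bayes factor, the success flag and the
cumulative 1-CHF-per-success reward.
"""

from rtdcm import attention_pair, run_session, validate
from rtdcm.synth import NoiseSpec, make_design, simulate_session

design = make_design("neurofeedback", n_trials=8)
series, _ = simulate_session(design, NoiseSpec(), seed=4)

pair = tuple(validate(m) for m in attention_pair())
events = run_session(series, design, pair=pair)

print("trial  cond  display      logBF  success  reward")
for e in events:
    print(f"{e.trial_index:5d}  {e.condition:4s}  "
          f"{e.display_word:4s} ({e.display_value:+d})  {e.logBF:+8.2f}  "
          f"{str(e.success):7s}  {e.reward_total:4.0f} CHF")
n_succ = sum(e.success for e in events)
print(f"\n{n_succ}/8 successful trials; positive logBF on aL and negative "
      "on aR count as success.")
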