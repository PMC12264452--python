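"""Simulate a 2-back run and score it: d', mean RT, change index.

The 2-back task presents 150 letters with 30% targets; performance is the
signal-detection sensitivity d' = Z(hit rate) - Z(false-alarm rate) and the
mean reaction time over correct responses.  The change index
X = (pre - post)/pre summarizes the pre-to-post speed-up.
"""

import numpy as np

import cerebwm as c
from cerebwm import behavior as bh

cfg = c.SimConfig(seed=42)
rng = np.random.default_rng(42)
pre = c.generate_behavior(cfg, group="rTMS5", session="pre", rng=rng)
post = c.generate_behavior(cfg, group="rTMS5", session="post", rng=rng)

s_pre = bh.summarize_session(pre)
s_post = bh.summarize_session(post)
x = bh.change_index(s_pre.mean_rt, s_post.mean_rt)

print(f"pre : d' = {s_pre.dprime:.3f}, mean correct RT = {s_pre.mean_rt:.3f} s "
      f"({s_pre.n_hits}/{s_pre.n_targets} hits, "
      f"{s_pre.n_false_alarms}/{s_pre.n_nontargets} false alarms)")
print(f"post: d' = {s_post.dprime:.3f}, mean correct RT = {s_post.mean_rt:.3f} s")
print(f"change index X = {x.x:.3f}")
print("X > 0 means the subject answered faster after stimulation; the "
      "simulated 5 Hz group carries a -0.112 s ground-truth RT shift.")
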