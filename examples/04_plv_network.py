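"""PLV connectivity and graph metrics on resting-state EEG.

Band-passes resting segments, extracts analytic-signal phases, builds
theta-band PLV matrices, keeps the strongest 30% of connections, and
reports the small-world metrics of the binary graphs.  The post session
carries a +0.15 theta-coupling increase on the long-range fronto-parietal
pairs; like the paired group analysis, the example averages a few subjects
because a single subject's mean-PLV estimate is noisier than the shift.
"""

import numpy as np

import cerebwm as c
from cerebwm import connectivity as con
from cerebwm.bands import DEFAULT_BANDS

cfg = c.SimConfig(n_channels=32, n_rest_segments=20)
montage = c.generate_montage(32)
n_subjects = 6

rows = {"pre": [], "post": []}
for s in range(n_subjects):
    rng = np.random.default_rng(100 + s)
    for session in ("pre", "post"):
        ep = c.generate_epochs(cfg, group="rTMS5", session=session,
                               kind="rest", rng=rng, montage=montage)
        m = con.band_plv(ep, DEFAULT_BANDS["theta"])
        gm = con.graph_metrics(con.proportional_threshold(m, density=0.30))
        rows[session].append((m.mean_plv(), gm.cp, gm.lp, gm.eglob,
                              gm.eloc_mean))

for session in ("pre", "post"):
    plv, cp, lp, eglob, eloc = np.mean(rows[session], axis=0)
    print(f"{session:<5} mean PLV = {plv:.3f} | Cp = {cp:.3f}  Lp = {lp:.3f}  "
          f"Eglob = {eglob:.3f}  Eloc = {eloc:.3f}   (mean of "
          f"{n_subjects} subjects)")

d = np.mean(rows["post"], axis=0)[0] - np.mean(rows["pre"], axis=0)[0]
print(f"\nmean theta PLV change (post - pre): {d:+.4f}")
print("The injected long-range coupling raises the group-average theta "
      "PLV; the graph metrics describe the 30%-density binary network "
      "(their changes carry no injected ground truth).")
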