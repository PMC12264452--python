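"""Event-related band power via the sliding Hanning-window spectrogram.

Computes trial-averaged power (3-30 Hz), normalizes it in dB against the
-200..0 ms baseline, and averages each band over the 50-350 ms analysis
window.  The simulated post session carries +1 dB of theta and alpha
oscillation amplitude.
"""

import numpy as np

import cerebwm as c
from cerebwm import timefreq as tf
from cerebwm.bands import DEFAULT_BANDS

cfg = c.SimConfig(n_channels=8, n_trials=60)
rng = np.random.default_rng(3)
freqs = np.arange(3.0, 30.5, 0.5)

rows = {}
for session in ("pre", "post"):
    ep = c.generate_epochs(cfg, group="rTMS5", session=session, rng=rng)
    tfr = tf.baseline_db(tf.spectrogram_hanning(ep, freqs=freqs))
    for name in ("theta", "alpha", "beta1", "beta2"):
        per_ch = tf.band_average(tfr, DEFAULT_BANDS[name])
        rows.setdefault(name, {})[session] = float(per_ch.mean())

print("band    pre (dB)  post (dB)  delta (dB)")
for name, v in rows.items():
    print(f"{name:<6} {v['pre']:9.3f} {v['post']:10.3f} "
          f"{v['post'] - v['pre']:10.3f}")
print("\nValues are dB relative to the pre-stimulus baseline, averaged over "
      "channels, band bins and 50-350 ms. Theta/alpha deltas are positive "
      "(injected, amplified by the larger evoked P150); the beta1 delta "
      "reflects spectral leakage from the alpha edge and the broadband "
      "evoked change, and beta2 stays near zero.")
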