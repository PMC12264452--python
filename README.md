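# cerebwm

EEG analysis of cerebellar repetitive transcranial magnetic stimulation
(rTMS) effects on working memory.

`cerebwm` is a Python library for the analysis chain of a five-arm pre/post
stimulation study (1, 5, 10, 20 Hz and sham rTMS over the cerebellum): it
scores 2-back working-memory behavior, extracts event-related potential
(ERP) component amplitudes, quantifies event-related oscillatory power,
infers phase-locking-value (PLV) brain networks with graph-theory metrics,
and tests everything with cluster-based permutation statistics and a
classical ANOVA/FDR layer. Because raw recordings of such studies are
rarely shareable, the package ships a first-class synthetic-data generator
that reproduces the statistical structure the analyses assume — 1000 Hz
EEG on a 10-10 montage, stimulus-locked components, band-limited bursts on
1/f noise, controllable inter-channel phase coupling, and per-group
pre/post effect deltas — so every stage is exercisable end-to-end and
validated by parameter recovery.

It is aimed at EEG researchers and methodologists who want a tested,
scriptable implementation of this analysis stack, or a ground-truth
simulator to benchmark their own.

## The quantities it computes

**Behavior.** Sensitivity d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate)
(rates of 0/1 corrected to 0.5/n and (n−0.5)/n), mean reaction time over
correct trials, and the change index X = (pre − post)/pre (positive =
faster after stimulation).

**ERP.** Trial averages with −200..0 ms baseline; windowed mean amplitudes
for N100 (75–125 ms), P150 (130–190 ms), N200 (210–290 ms), P300
(280–380 ms) over the fronto-central electrodes FC1/FCz/FC2; difference
waves (post − pre).

**Oscillations.** Sliding Hanning-window spectrograms (3–80 Hz, 0.5 Hz
steps, 10 ms resolution), dB baseline `10·log10(P / P̄_baseline)`, band
averages (θ 4–8, α 8–13, β1 13–20, β2 20–30, γ 30–80 Hz) over 50–350 ms.

**Networks.** PLV(i,j) = |⟨exp(i(φᵢ−φⱼ))⟩ₜ| from Hilbert phases of
band-passed resting EEG; proportional thresholding (top 30% of
connections); clustering coefficient Cp, characteristic path length Lp,
global efficiency Eglob, local efficiency Eloc.

**Statistics.** Cluster-mass permutation tests over electrodes × time
(clusters of ≥ 2 adjacent electrodes, sign-flip or relabelling nulls,
per-tail α = 0.025), Benjamini–Hochberg FDR, Bonferroni, Shapiro–Wilk
normality gating to nonparametric alternatives, Pearson correlation.

See `docs/methods.md` for the full model description and numerical
conventions.

## Worked example

Score the oscillatory response of one simulated 5 Hz-group subject
(`examples/03_oscillatory_power.py`):

```python
import numpy as np
import cerebwm as c
from cerebwm import timefreq as tf
from cerebwm.bands import DEFAULT_BANDS

cfg = c.SimConfig(n_channels=8, n_trials=60)
rng = np.random.default_rng(3)
freqs = np.arange(3.0, 30.5, 0.5)
for session in ("pre", "post"):
    ep = c.generate_epochs(cfg, group="rTMS5", session=session, rng=rng)
    tfr = tf.baseline_db(tf.spectrogram_hanning(ep, freqs=freqs))
    alpha = tf.band_average(tfr, DEFAULT_BANDS["alpha"]).mean()
    print(session, round(float(alpha), 3), "dB")
```

prints (the full script's table)

```
band    pre (dB)  post (dB)  delta (dB)
theta      8.709     10.336      1.627
alpha      9.582     11.343      1.760
beta1      5.256      6.479      1.223
beta2      2.271      2.601      0.330
```

theta and alpha power rise by well over 1 dB after the simulated 5 Hz
stimulation — the injected oscillation gain plus the evoked P150 increase,
which also contributes band power — while beta2 barely moves (the beta1
delta is spectral leakage from the alpha edge). Each value is dB relative
to the pre-stimulus baseline, averaged over channels, band bins and the
50–350 ms window.

The other example scripts cover behavioral scoring (`01`), ERP components
(`02`), PLV networks (`04`), the cluster permutation test (`05`) and the
complete multi-group pipeline with its structured report (`06`).

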