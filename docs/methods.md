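# Methods

`cerebwm` implements the complete analysis chain for a five-arm pre/post
cerebellar stimulation study of working memory — behavioral scoring of the
2-back task, event-related potentials (ERPs), event-related oscillatory
power, phase-locking-value (PLV) brain networks with graph-theory metrics,
and cluster-based permutation statistics — together with a synthetic-data
generator that injects known group effects so every stage can be validated
by parameter recovery. This note describes the models, the defaults and why
they were chosen, and what the synthetic validation does and does not show.

## Study structure

Five stimulation groups are modeled (1, 5, 10, 20 Hz and sham), each
subject measured before ("pre") and after ("post") the intervention, with
resting-state EEG, task EEG during a 2-back run, and a behavioral log.
Between-group statistics treat sessions/subjects as independent records;
the crossover assignment of real participants to two conditions is not
modeled beyond this.

## Behavioral scoring

The 2-back run has 150 trials with 30% targets (letters A–J; a target
repeats the letter shown two trials earlier). Sensitivity is the
signal-detection measure

    d' = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate),

with hit rate computed on targets and false-alarm rate on non-targets.
Rates of exactly 0 or 1 are corrected to `0.5/n` and `(n−0.5)/n` before the
inverse-normal transform (log-linear-style correction) so d′ stays finite;
which correction the original analysis used is not documented, so this
standard one was chosen. Mean reaction time (RT) is computed over correct
trials only. The behavioral change index is

    X = (pre − post) / pre,

signed so that an RT reduction is positive; the sign convention follows the
tabulated group values (positive entries for improvements) rather than the
literal (post−pre)/pre formula, which is available behind a `literal` flag.
X is a per-subject quantity; group summaries are means of per-subject
ratios, not ratios of group means.

Group comparisons use one-way ANOVA, replaced by Kruskal–Wallis whenever a
Shapiro–Wilk test (α = 0.05) rejects normality in any group, with
Bonferroni-corrected pairwise tests against the sham reference.

## ERP analysis

Epochs span −200 to +800 ms around the stimulus at 1000 Hz. An optional
minimal cleaning stage applies a zero-phase 1–80 Hz band-pass (4th-order
Butterworth, forward–backward so latencies are unshifted), an optional
50 Hz notch, and drops trials with any sample above ±100 µV. ERPs are trial
means with the −200..0 ms baseline mean subtracted per channel. Component
amplitudes are **windowed means** (not peak picks — more robust, and the
standard reading of windowed "amplitude") over N100 75–125 ms, P150
130–190 ms, N200 210–290 ms, P300 280–380 ms, averaged over the
fronto-central reporting electrodes FC1/FCz/FC2. Intervals are closed and
the t = 0 sample belongs to the post-stimulus side. Pre/post contrasts use
difference waves (post − pre); by linearity the windowed amplitude of the
difference equals the difference of windowed amplitudes.

Note that a windowed mean of a peaked deflection is smaller than its peak
amplitude by the window factor (for a Gaussian template of sd σ centered at
μ, the factor is `σ√(2π)(Φ(b)−Φ(a))/width`); recovery tests compare against
this closed form rather than the raw injected peak.

## Time-frequency analysis

Oscillatory power is estimated with a sliding Hanning-window short-time
transform: per trial and channel, the signal is convolved with a
Hann-tapered complex exponential at each frequency (3–80 Hz in 0.5 Hz
steps), magnitudes are squared, normalized so a sinusoid of amplitude A
yields power A², and averaged across trials ("total" power — evoked plus
induced). The time grid is 10 ms.

Window length is frequency-adaptive: 4 cycles per frequency, floored at
100 ms and capped at 250 ms, with frequencies too low for the cap given
exactly one cycle. The cap matters: with a −200..0 ms baseline, windows
longer than ~250 ms leave almost no time bin whose window fits inside the
pre-stimulus interval, and those that remain smear post-stimulus activity
into the baseline. A fixed window length is available; requesting a
frequency that completes less than one cycle in a fixed window is an error.
Time bins whose window extends beyond the epoch are NaN, never zero-padded.

Power is baselined in decibels, `10·log10(power / mean baseline power)`
per channel and frequency over −200..0 ms, then averaged within bands —
theta 4–8, alpha 8–13, beta1 13–20, beta2 20–30, gamma 30–80 Hz (half-open
intervals so shared edges are not double-counted; 80 Hz belongs to gamma) —
and over the 50–350 ms analysis window. Whether the original analysis
averaged trials before or after the log transform is not documented; power
is averaged across trials first, then log-transformed, which is the
usual definition of total power in dB.

## PLV networks and graph metrics

Instantaneous phase comes from the analytic signal (Hilbert transform) of
the zero-phase band-passed data; 100 ms at each epoch edge is flagged
invalid for filter and Hilbert transients. For channels i, j the
phase-locking value is

    PLV(i,j) = | ⟨exp(i(φᵢ(t) − φⱼ(t)))⟩ₜ |,

computed per segment (non-overlapping 2 s resting segments by default) and
averaged across segments; it lies in [0, 1] and equals 1 for identical or
constant-lag signals. The symmetric PLV matrix is binarized by proportional
thresholding: the strongest 30% of the n(n−1)/2 connections become edges,
with ties broken deterministically by weight then lexicographic pair order.

Binary graph metrics: mean clustering coefficient Cp (triangles over
possible triangles per node, 0 for degree < 2); characteristic path length
Lp (mean shortest-path length over reachable pairs, with a connectedness
flag — this avoids infinite Lp on disconnected graphs); global efficiency
Eglob (mean of 1/distance over ordered pairs, 0 for unreachable pairs,
which handles disconnection naturally); and local efficiency Eloc(i)
(global efficiency of the subgraph induced by i's neighbours, 0 for fewer
than 2 neighbours). Implementations run on networkx graphs; the test suite
verifies them exactly against an independent brute-force oracle
(Floyd–Warshall distances, direct triangle enumeration) on a thousand
random graphs of ≤ 7 nodes.

## Cluster-based permutation statistics

Channel×time maps are compared with a nonparametric cluster-mass test:

1. pointwise t statistics (paired, or pooled-variance independent);
2. points with |t| above the two-sided α = 0.05 critical value form
   clusters, connected through the electrode neighbourhood graph within a
   time bin and through time-adjacency within an electrode;
3. clusters spanning fewer than two distinct electrodes are discarded;
4. each cluster is scored by the sum of its t values ("maxsum");
5. the null distribution of the maximum |cluster mass| is built from
   random sign flips of subject difference maps (paired) or full label
   reshuffles (independent), and each observed cluster gets the
   +1-corrected Monte Carlo p-value p = (1 + #{null ≥ observed}) /
   (1 + n_permutations), so p is never exactly zero;
6. positive and negative clusters are each tested at α = 0.025, a 0.05
   two-tailed family-wise level.

Electrode neighbourhoods are distance-based: pairs within 1.3× the median
nearest-neighbour distance of the montage (a template neighbourhood could
be substituted; the distance rule is the documented default). A
small-variance guard (ε = 10⁻²⁴ in the t denominator) keeps degenerate
points finite. Between-group contrasts of pre-to-post change are
independent-design tests on subject-level difference maps. Fixed seeds make
all permutation p-values reproducible.

The classical layer provides Benjamini–Hochberg FDR (step-up; rejections
always include Bonferroni's at the same level), Bonferroni, the
Shapiro–Wilk normality gate, and Pearson correlation with a two-tailed
t-based p.

## Synthetic data: what it emulates

Each simulated channel/trial is the sum of

* **1/f background noise** — white noise spectrally shaped to `f^(−α/2)`
  amplitude (α = 1 by default), scaled to 2 µV SD;
* **ERP templates** — Gaussian bumps `A·exp(−(t−μ)²/2σ²)` at N100 (−3 µV,
  100 ms, σ 12), P150 (+4 µV, 160 ms, σ 15), N200 (−2.5 µV, 250 ms, σ 20),
  P300 (+3.5 µV, 330 ms, σ 30), with a fronto-central topography decaying
  with distance from FCz (a pure Gaussian was preferred over windowed
  half-sine shapes for its analytic peak location and closed-form window
  integral, which the oracle tests exploit);
* **band-limited oscillations** — amplitudes θ 2.0, α 3.0, β1 0.8, β2 0.5,
  γ 0.4 µV (alpha dominant, prominent frontal-midline theta, as in task
  EEG; the amplitudes are set high enough relative to the in-band 1/f
  noise floor that a nominal dB injection materializes in measured total
  power within roughly 20%); in task epochs they are event-related bursts under a Gaussian
  envelope (center 250 ms, σ 70 ms, gated to t ≥ 0) so that baseline power
  is noise-only and a dB change is measurable; in resting epochs they run
  continuously. Uncoupled channels draw an independent random frequency
  inside the band per channel and trial, so their phase differences drift
  and the no-coupling PLV stays near the sampling floor;
* **phase coupling** — designated channel *pairs* each share a carrier (an
  independent random in-band frequency and phase per trial), both members
  adding slow Gaussian phase jitter of SD `√(−ln PLV)`; the pairwise phase
  difference is then N(0, −2 ln PLV) and the sample-level PLV equals the
  target (the band-pass/Hilbert estimate is close but not exact, so
  coupling recovery is tested as a monotone effect, not an equality).
  Distinct carriers keep different pairs mutually unlocked, so coupling
  does not transitively form cliques. Default: θ-band coupling at PLV 0.45
  on 14 disjoint long-range fronto-parietal/occipital pairs (realizable on
  montages of ≥ ~26 channels; smaller montages need explicit pairs);
* **volume conduction** — every electrode finally sees a distance-weighted
  Gaussian mixture of its neighbours (σ = 3 cm, row-normalized, disabled
  with `mixing_sigma_m=None`). This gives PLV matrices their realistic
  distance dependence, so thresholded networks are lattice-like and
  injected long-range coupling acts as small-world shortcuts.

The default montage is a 32-channel 10-10 subset grown outward from the
fronto-central patch (so any prefix of the channel list is spatially
contiguous and every electrode has a neighbour); the recording cap's 69+2
channels are supported but not the desk-scale default. Behavioral responses
follow configured hit (0.85) and false-alarm (0.10) rates; RTs are
shifted-lognormal (shift 0.25 s, σ_ln 0.35) with mean 0.80 s pre.

**Injected group effects** (post-session deltas) default to the study's
qualitative findings: all groups speed up (training effect; −0.106, −0.112,
−0.072, −0.093, −0.051 s for 1/5/10/20 Hz/sham), and the 5 Hz group
additionally gains +2 µV of P150, +1 dB of θ and α oscillation power, and
+0.15 of θ-band PLV; the 10 Hz group gains 1 µV of N100 (more negative).
Letters are assigned uniformly at random subject to the target-fraction
constraint.

**What the generator does not emulate:** TMS pulse artifacts, ocular or
muscular artifacts, inter-subject amplitude variability beyond sampling
noise, volume conduction or head-model forward projection, non-stationary
background spectra. Passing recovery tests therefore show that the
analysis chain estimates what was injected under clean, exchangeable
conditions; they do not certify performance on real recordings with
artifact structure or between-subject heterogeneity.

## Numerical choices and problem sizes

* Zero-phase (forward-backward) IIR filtering throughout; 4th-order
  Butterworth band-passes.
* dB baseline requires a strictly positive baseline mean; zero or negative
  means raise.
* Proportional-threshold quota: `round(density · n(n−1)/2)` edges,
  deterministic tie-break.
* Permutation engines and generators take explicit seeds; fixed seed ⇒
  byte-identical reports.
* Simulated validation runs use desk-scale sizes chosen to keep the whole
  suite interactive: 8–16 channels, 20–60 task trials, 8–12 subjects per
  group, 200–500 permutations (the method's reference permutation count is
  5000, and 30 subjects per group were measured in the study this emulates;
  both are plain config parameters). Null calibration uses 500 simulated
  studies at 500 permutations; recovery uses 50 replicates per effect.

## Known limitations

* **Binary global efficiency is not a reliable recovery target for
  injected synchrony.** At a fixed 30% density the binarized graph depends
  only on the rank order of PLV values: a uniform synchrony increase does
  not reorder ranks at all, and a concentrated increase (clique or pair
  set) pulls threshold edges into the strengthened subset, displacing
  mid-range lattice edges — which lowers, rather than raises, global
  efficiency. In simulation, injected θ coupling raises mean θ-PLV in
  essentially every replicate, while Δ-Eglob of the thresholded graph
  hovers at or slightly below zero. Network validation therefore targets
  mean PLV; Eglob, Lp, Cp and Eloc are computed and reported but their
  pre/post changes carry no injected ground truth. An empirical
  global-efficiency increase in real data presumably reflects spatial
  reorganization this generator does not model.
* Lp on disconnected graphs averages finite distances only; comparing Lp
  across graphs with different connectedness is then not meaningful (the
  flag is reported for this reason).
* The PLV coupling calibration is exact at the phase-sample level but only
  approximate after band-pass filtering; injected coupling values should
  be read as targets, not measured ground truth.
* The spectral estimator's adaptive window cap trades frequency resolution
  below ~16 Hz for baseline validity; analyses needing finer low-frequency
  resolution should extend the epoch and pass a longer `win_max_s`.
* Serialization covers the HDF5 epoch container and CSV tables; EDF export
  is not provided.
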