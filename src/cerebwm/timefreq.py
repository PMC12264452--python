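"""Event-related oscillatory power via sliding Hanning-window spectrograms.

Power is estimated per trial by convolving each channel with a
Hanning-tapered complex exponential per frequency (the sliding-window
short-time transform), squaring, and averaging across trials — "total"
power, capturing evoked and induced activity alike.  The default analysis
grid is 3-80 Hz in 0.5 Hz steps at 10 ms time resolution; power is
expressed in dB relative to the mean of the -200..0 ms pre-stimulus
baseline and averaged within the theta/alpha/beta1/beta2/gamma bands.

Window length is frequency-adaptive by default (4 cycles, floored at
100 ms) so low frequencies keep enough cycles while high frequencies keep
temporal resolution.  The cap is 250 ms: with a -200..0 ms baseline, any
longer window would leave almost no valid baseline bin and would smear
post-stimulus activity into the ones that remain.  A fixed length may be
given instead.  Time bins whose window would extend beyond the epoch are
NaN, never silently zero-padded.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .bands import BandDefinition
from .containers import EpochSet, TFR

__all__ = ["default_freq_grid", "spectrogram_hanning", "baseline_db", "band_average"]


def default_freq_grid() -> np.ndarray:
    """3 to 80 Hz inclusive in 0.5 Hz steps."""
    return np.arange(3.0, 80.0 + 1e-9, 0.5)


def _window_samples(freq: float, fs: float, cycles: float, win_min_s: float,
                    win_max_s: float, fixed_win_s: float | None) -> int:
    if fixed_win_s is not None:
        length_s = fixed_win_s
        if freq * length_s < 1.0:
            raise ValueError(
                f"frequency {freq} Hz completes under one cycle in a "
                f"{length_s:.3f} s window; lengthen the window or raise the "
                "lowest frequency")
    else:
        # frequencies below 1/win_max get exactly one cycle so they stay
        # resolvable; everything else follows the cycles/f rule
        length_s = max(float(np.clip(cycles / freq, win_min_s, win_max_s)),
                       1.0 / freq)
    n = int(round(length_s * fs))
    return n + 1 - n % 2  # odd length centers the window on the output bin


def spectrogram_hanning(epochs: EpochSet, freqs: np.ndarray | None = None,
                        step_ms: float = 10.0, *, cycles: float = 4.0,
                        win_min_s: float = 0.1, win_max_s: float = 0.25,
                        fixed_win_s: float | None = None) -> TFR:
    """Trial-averaged sliding Hanning-window power, channels x freqs x times."""
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    fs, n_samp = epochs.fs, epochs.n_samples
    if freqs.max() >= fs / 2:
        raise ValueError("frequencies must stay below Nyquist")

    step = max(1, int(round(step_ms / 1000.0 * fs)))
    out_idx = np.arange(0, n_samp, step)
    times = epochs.times[out_idx]

    n_ch, n_tr = epochs.n_channels, epochs.n_trials
    flat = epochs.data.transpose(0, 2, 1).reshape(n_ch * n_tr, n_samp)
    power = np.empty((n_ch, freqs.size, out_idx.size))
    for fi, f in enumerate(freqs):
        n_win = _window_samples(f, fs, cycles, win_min_s, win_max_s, fixed_win_s)
        if n_win > n_samp:
            raise ValueError(
                f"analysis window for {f} Hz ({n_win} samples) exceeds the epoch")
        taper = np.hanning(n_win)
        t_k = (np.arange(n_win) - n_win // 2) / fs
        kernel = taper * np.exp(-2j * np.pi * f * t_k)
        conv = signal.fftconvolve(flat, kernel[None, :], mode="same", axes=-1)
        p = (np.abs(conv) / (taper.sum() / 2.0)) ** 2  # sinusoid amp A -> A^2
        p = p.reshape(n_ch, n_tr, n_samp).mean(axis=1)
        half = n_win // 2
        valid = (out_idx >= half) & (out_idx < n_samp - half)
        col = p[:, out_idx]
        col[:, ~valid] = np.nan
        power[:, fi, :] = col
    return TFR(power, freqs, times, epochs.ch_names, baseline_mode="none")


def baseline_db(tfr: TFR, baseline: tuple[float, float] = (-0.2, 0.0)) -> TFR:
    """Decibel normalization: 10*log10(power / mean baseline power).

    The baseline mean is taken per channel and frequency over the valid
    time bins inside the closed interval.
    """
    if tfr.baseline_mode != "none":
        raise ValueError("TFR is already baseline-normalized")
    dt = np.median(np.diff(tfr.times)) if tfr.times.size > 1 else 0.0
    mask = (tfr.times >= baseline[0] - dt / 2) & (tfr.times <= baseline[1] + dt / 2)
    if not mask.any():
        raise ValueError("baseline interval contains no time bins")
    base = tfr.data[:, :, mask]
    if np.all(np.isnan(base)):
        raise ValueError("no valid baseline bins (all inside the edge region)")
    with np.errstate(invalid="ignore"):
        base_mean = np.nanmean(base, axis=2, keepdims=True)
    if np.any(base_mean <= 0):
        raise ValueError("baseline mean power must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        db = 10.0 * np.log10(tfr.data / base_mean)
    return TFR(db, tfr.freqs.copy(), tfr.times.copy(), tfr.ch_names,
               baseline_mode="dB")


def band_average(tfr: TFR, band: BandDefinition,
                 time_window: tuple[float, float] = (0.05, 0.35)) -> np.ndarray:
    """Per-channel mean power over the band's bins and the time window.

    NaN edge bins are excluded; the selection must contain at least one
    valid bin.  The default window 50-350 ms targets the early
    working-memory response.
    """
    fmask = band.mask(tfr.freqs)
    if not fmask.any():
        raise ValueError(f"no frequency bins inside band {band.label!r}")
    dt = np.median(np.diff(tfr.times)) if tfr.times.size > 1 else 0.0
    tmask = (tfr.times >= time_window[0] - dt / 2) & (tfr.times <= time_window[1] + dt / 2)
    if not tmask.any():
        raise ValueError("time window contains no bins")
    sel = tfr.data[:, fmask, :][:, :, tmask]
    if np.all(np.isnan(sel)):
        raise ValueError("selection contains no valid bins")
    with np.errstate(invalid="ignore"):
        return np.nanmean(sel, axis=(1, 2))
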