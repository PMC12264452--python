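"""ERP preprocessing, averaging, component amplitudes and difference waves.

Components are scored as the mean amplitude over fixed latency windows —
N100 75-125 ms, P150 130-190 ms, N200 210-290 ms, P300 280-380 ms — on the
average of a channel subset (fronto-central FC1/FCz/FC2 for reporting).
Windows are closed intervals in milliseconds relative to stimulus onset;
the t=0 sample belongs to the post-stimulus side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .containers import EpochSet

__all__ = [
    "ComponentWindow",
    "COMPONENT_WINDOWS",
    "ERPWaveform",
    "preprocess",
    "average_erp",
    "component_amplitude",
    "difference_wave",
]

BASELINE = (-0.2, 0.0)  # seconds


@dataclass(frozen=True)
class ComponentWindow:
    label: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError("window start must precede end")


COMPONENT_WINDOWS: dict[str, ComponentWindow] = {
    "N100": ComponentWindow("N100", 75.0, 125.0),
    "P150": ComponentWindow("P150", 130.0, 190.0),
    "N200": ComponentWindow("N200", 210.0, 290.0),
    "P300": ComponentWindow("P300", 280.0, 380.0),
}


@dataclass
class ERPWaveform:
    """Trial-averaged, baseline-corrected waveform: channels x time (µV)."""

    data: np.ndarray
    times: np.ndarray  # seconds
    ch_names: tuple[str, ...]
    n_trials: int
    group: str | None = None
    session: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape != (len(self.ch_names), self.times.size):
            raise ValueError("data must be (channels, times)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        self.ch_names = tuple(self.ch_names)

    @property
    def times_ms(self) -> np.ndarray:
        return self.times * 1000.0


@dataclass(frozen=True)
class PreprocessReport:
    n_trials_in: int
    n_trials_dropped: int
    dropped_indices: tuple[int, ...]


def preprocess(epochs: EpochSet, *, l_freq: float = 1.0, h_freq: float = 80.0,
               notch_hz: float | None = None, reject_uv: float = 100.0,
               ) -> tuple[EpochSet, PreprocessReport]:
    """Minimal documented cleaning: band-pass, optional notch, amplitude reject.

    Filtering is zero-phase (forward-backward 4th-order Butterworth) so
    component latencies are preserved.  Trials containing any sample with
    |amplitude| above ``reject_uv`` (after filtering) are dropped.
    """
    nyq = epochs.fs / 2.0
    if not (0 < l_freq < h_freq < nyq):
        raise ValueError("need 0 < l_freq < h_freq < Nyquist")
    sos = signal.butter(4, [l_freq, h_freq], btype="bandpass", fs=epochs.fs,
                        output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=1)
    if notch_hz is not None:
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=epochs.fs)
        data = signal.filtfilt(b, a, data, axis=1)

    peak = np.abs(data).max(axis=(0, 1))  # per trial
    keep = peak <= reject_uv
    if not keep.any():
        raise ValueError("all trials rejected by the amplitude threshold")
    dropped = tuple(int(i) for i in np.flatnonzero(~keep))
    out = replace(epochs, data=data[:, :, keep],
                  meta={**epochs.meta, "n_dropped": len(dropped)})
    report = PreprocessReport(epochs.n_trials, len(dropped), dropped)
    return out, report


def average_erp(epochs: EpochSet, baseline: tuple[float, float] = BASELINE,
                ) -> ERPWaveform:
    """Trial mean per channel after subtracting the baseline-interval mean.

    The baseline mean is computed per channel on the trial average, so the
    resulting waveform averages to ~0 inside the baseline interval.
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    t = epochs.times
    if baseline[0] < t[0] - 0.5 / epochs.fs or baseline[1] > t[-1] + 0.5 / epochs.fs:
        raise ValueError("baseline interval outside the epoch")
    mask = epochs.time_mask(*baseline)
    if not mask.any():
        raise ValueError("baseline interval contains no samples")
    mean = epochs.data.mean(axis=2)
    mean -= mean[:, mask].mean(axis=1, keepdims=True)
    return ERPWaveform(mean, t, epochs.ch_names, epochs.n_trials,
                       group=epochs.group, session=epochs.session)


def component_amplitude(erp: ERPWaveform, window: ComponentWindow | str,
                        channels: tuple[str, ...] = ("FC1", "FCz", "FC2"),
                        ) -> float:
    """Mean amplitude (µV) over the closed window and the channel subset."""
    if isinstance(window, str):
        window = COMPONENT_WINDOWS[window]
    if not channels:
        raise ValueError("channel subset must be non-empty")
    lut = {c: i for i, c in enumerate(erp.ch_names)}
    try:
        idx = [lut[c] for c in channels]
    except KeyError as err:
        raise KeyError(f"channel {err.args[0]!r} not in waveform") from None
    tms = erp.times_ms
    dt_ms = np.median(np.diff(tms))
    if window.start_ms < tms[0] - dt_ms / 2 or window.end_ms > tms[-1] + dt_ms / 2:
        raise ValueError("component window outside the epoch time axis")
    mask = (tms >= window.start_ms - dt_ms / 2) & (tms <= window.end_ms + dt_ms / 2)
    return float(erp.data[np.ix_(idx, np.flatnonzero(mask))].mean())


def difference_wave(post: ERPWaveform, pre: ERPWaveform) -> ERPWaveform:
    """Pointwise post - pre waveform (identical channels and time axes)."""
    if post.ch_names != pre.ch_names:
        raise ValueError("channel sets differ")
    if post.times.shape != pre.times.shape or not np.allclose(post.times, pre.times):
        raise ValueError("time axes differ")
    return ERPWaveform(post.data - pre.data, post.times.copy(), post.ch_names,
                       n_trials=min(post.n_trials, pre.n_trials),
                       group=post.group, session="post-pre")
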