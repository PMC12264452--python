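"""Core in-memory containers shared by every analysis stage.

The containers are deliberately thin wrappers around numpy arrays with the
axis metadata (sampling rate, epoch time axis, channel labels, study labels)
that the ERP, time-frequency, connectivity and statistics stages all need.
Epoch data are stored as ``channels x samples x trials`` in microvolts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np

__all__ = ["Montage", "EpochSet", "TFR"]


@dataclass(frozen=True)
class Montage:
    """Electrode labels with 3-D positions (meters, head frame).

    The montage is the source of the spatial adjacency used by the
    cluster-based permutation test and of the fronto-central reporting
    subset {FC1, FCz, FC2}.
    """

    ch_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)

    #: electrodes averaged for ERP waveform reporting
    REPORTING_CHANNELS = ("FC1", "FCz", "FC2")

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if len(self.ch_names) != pos.shape[0]:
            raise ValueError("ch_names and positions length mismatch")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("duplicate channel labels")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "ch_names", tuple(self.ch_names))

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def index(self, names: Sequence[str]) -> np.ndarray:
        """Indices of ``names`` in montage order; KeyError if absent."""
        lut = {c: i for i, c in enumerate(self.ch_names)}
        try:
            return np.array([lut[n] for n in names], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not in montage") from None

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix (meters)."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff**2).sum(-1))


@dataclass
class EpochSet:
    """Stimulus-locked EEG epochs: ``channels x samples x trials`` in µV."""

    data: np.ndarray
    fs: float
    tmin: float  # seconds, start of the epoch relative to stimulus onset
    ch_names: tuple[str, ...]
    group: str | None = None
    session: str | None = None
    condition: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x samples x trials")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.ch_names = tuple(self.ch_names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to stimulus onset."""
        return self.tmin + np.arange(self.n_samples) / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return self.times * 1000.0

    def time_mask(self, start_s: float, stop_s: float) -> np.ndarray:
        """Boolean mask of samples inside the closed interval [start, stop]."""
        t = self.times
        eps = 0.5 / self.fs
        return (t >= start_s - eps) & (t <= stop_s + eps)

    def pick(self, names: Sequence[str]) -> "EpochSet":
        lut = {c: i for i, c in enumerate(self.ch_names)}
        idx = [lut[n] for n in names]
        return replace(self, data=self.data[idx], ch_names=tuple(names))

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), meta=dict(self.meta))

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        """Write to an HDF5 container (array + JSON-encoded metadata)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["fs"] = self.fs
            f.attrs["tmin"] = self.tmin
            f.attrs["ch_names"] = json.dumps(list(self.ch_names))
            f.attrs["labels"] = json.dumps(
                {"group": self.group, "session": self.session, "condition": self.condition}
            )
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            labels = json.loads(f.attrs["labels"])
            return cls(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                tmin=float(f.attrs["tmin"]),
                ch_names=tuple(json.loads(f.attrs["ch_names"])),
                meta=json.loads(f.attrs["meta"]),
                **labels,
            )


@dataclass
class TFR:
    """Time-frequency power, ``channels x frequencies x times``.

    ``baseline_mode`` is ``"none"`` for raw power (µV², non-negative) or
    ``"dB"`` after decibel baseline normalization.  Time bins whose analysis
    window extended beyond the epoch are NaN (never silently zero-padded).
    """

    data: np.ndarray
    freqs: np.ndarray  # Hz
    times: np.ndarray  # seconds relative to stimulus onset
    ch_names: tuple[str, ...]
    baseline_mode: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape != (len(self.ch_names), self.freqs.size, self.times.size):
            raise ValueError("data shape must be (channels, freqs, times)")
        if self.baseline_mode not in ("none", "dB"):
            raise ValueError("baseline_mode must be 'none' or 'dB'")
        self.ch_names = tuple(self.ch_names)

    def copy(self) -> "TFR":
        return TFR(self.data.copy(), self.freqs.copy(), self.times.copy(),
                   self.ch_names, self.baseline_mode)
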