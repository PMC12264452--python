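"""Canonical frequency-band definitions for the working-memory analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BandDefinition", "DEFAULT_BANDS"]

FREQ_MIN, FREQ_MAX = 3.0, 80.0


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[low, high)`` in Hz.

    Band membership is half-open so that shared boundaries (8 Hz, 13 Hz,
    20 Hz, 30 Hz) are never double-counted; the topmost band additionally
    includes its upper edge so the 80 Hz bin belongs to gamma.
    """

    label: str
    low: float
    high: float
    closed_high: bool = False

    def __post_init__(self) -> None:
        if not (FREQ_MIN <= self.low < self.high <= FREQ_MAX):
            raise ValueError(
                f"band [{self.low}, {self.high}] must satisfy "
                f"{FREQ_MIN} <= low < high <= {FREQ_MAX}"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequency bins whose center lies in the band."""
        freqs = np.asarray(freqs, dtype=float)
        m = (freqs >= self.low) & (freqs < self.high)
        if self.closed_high:
            m |= np.isclose(freqs, self.high)
        return m


DEFAULT_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta1": BandDefinition("beta1", 13.0, 20.0),
    "beta2": BandDefinition("beta2", 20.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 80.0, closed_high=True),
}
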