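"""Multichannel continuous recording container."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """A samples x channels matrix with sampling metadata.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
    rate_hz : float
        Sampling rate.
    labels : list of str, optional
        Channel labels; defaults to ``ch00, ch01, ...``.
    units : str
        Physical units of the samples (arbitrary for synthetic data).
    """

    data: np.ndarray
    rate_hz: float
    labels: list[str] = field(default=None)
    units: str = "arb"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("data must be a samples x channels matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.labels is None:
            self.labels = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("label count does not match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channel(self, i: int) -> np.ndarray:
        return self.data[:, i]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(data, self.rate_hz, list(self.labels), self.units)
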