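"""Uniformly sampled membrane-current records."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Trace:
    """A uniformly sampled current record.

    Parameters
    ----------
    samples : array-like
        Current samples in pA (inward currents negative).
    dt : float
        Sample interval in ms.
    label : str
        Free-text description (cell id, condition, ...).
    """

    samples: np.ndarray
    dt: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a Trace needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Trace samples must be finite")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms (first sample at t = 0)."""
        return np.arange(self.n) * self.dt
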