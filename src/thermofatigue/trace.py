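"""Per-ROI mean-temperature time series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ROITrace:
    """Mean temperature of one region of interest, sampled at a fixed rate.

    Attributes
    ----------
    label : name of the region (e.g. "Exercised Leg").
    values : temperatures in degrees Celsius, one per frame.
    fs : sampling rate in Hz.
    t0_s : time of the first sample in seconds (default 0).
    """

    label: str
    values: np.ndarray
    fs: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trace {self.label!r} contains non-finite values")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0_s + np.arange(self.values.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    def window_slice(self, start_s: float, end_s: float) -> slice:
        """Sample slice covering [start_s, end_s); count = round((end-start)*fs).

        Raises ValueError when the window does not lie inside the trace.
        """
        i0 = int(round((start_s - self.t0_s) * self.fs))
        n = int(round((end_s - start_s) * self.fs))
        if i0 < 0 or i0 + n > self.values.size:
            raise ValueError(
                f"window [{start_s}, {end_s}] s outside trace {self.label!r} "
                f"([{self.t0_s}, {self.t0_s + self.duration_s}] s)"
            )
        return slice(i0, i0 + n)

    def window_values(self, start_s: float, end_s: float) -> np.ndarray:
        return self.values[self.window_slice(start_s, end_s)]
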