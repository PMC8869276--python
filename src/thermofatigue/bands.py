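"""Canonical vasomotion frequency bands of skin-temperature oscillations.

Skin blood flow oscillates in spectral intervals that are conventionally
attributed to distinct physiological regulators: microvascular metabolic
activity, intrinsic neuronal (neurogenic) activity, smooth-muscle (myogenic)
activity of arterioles, respiration, and cardiac pulsation. The five bands
tile the interval [0.003, 1] Hz contiguously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class FrequencyBand:
    """A labelled frequency interval [f_lo, f_hi] in Hz."""

    label: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.label!r}: need 0 < f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi}]"
            )

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    @property
    def geometric_centre(self) -> float:
        return math.sqrt(self.f_lo * self.f_hi)

    def contains(self, f: float, strict: bool = False) -> bool:
        if strict:
            return self.f_lo < f < self.f_hi
        return self.f_lo <= f <= self.f_hi


METABOLIC = FrequencyBand("metabolic", 0.003, 0.02)
NEUROGENIC = FrequencyBand("neurogenic", 0.02, 0.04)
MYOGENIC = FrequencyBand("myogenic", 0.04, 0.15)
RESPIRATORY = FrequencyBand("respiratory", 0.15, 0.5)
CARDIAC = FrequencyBand("cardiac", 0.5, 1.0)

#: The canonical five bands, in ascending frequency order.
CANONICAL_BANDS: tuple[FrequencyBand, ...] = (
    METABOLIC,
    NEUROGENIC,
    MYOGENIC,
    RESPIRATORY,
    CARDIAC,
)

BANDS_BY_LABEL: dict[str, FrequencyBand] = {b.label: b for b in CANONICAL_BANDS}

BAND_LABELS: tuple[str, ...] = tuple(b.label for b in CANONICAL_BANDS)
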