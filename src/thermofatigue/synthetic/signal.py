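"""Generative model for a single ROI temperature trace.

The trace is the sum of
  * a continuous piecewise-linear trend (one slope per phase label),
  * band-limited sinusoidal oscillators, separately specifiable for the
    baseline ("pre") and recovery ("post") epochs,
  * i.i.d. Gaussian sensor noise at the thermal camera's noise floor
    (NETD, about 0.03 degC).

The piecewise-linear trend makes the injected pre/post temperature change
exactly computable, and the oscillator amplitudes make the injected band
power exactly A^2/2 per oscillator, so both feature families have closed-form
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..bands import BANDS_BY_LABEL, FrequencyBand
from ..timeline import SessionTimeline
from ..trace import ROITrace

#: Physiological clamp applied to generated temperatures, degC.
TEMP_CLAMP = (20.0, 45.0)

#: Sensor noise floor (NETD) used as the default noise SD, degC.
DEFAULT_NOISE_SD = 0.03


@dataclass(frozen=True)
class BandOscillator:
    """A sinusoid confined to one vasomotion band.

    ``frequency=None`` places the tone at the band's geometric centre,
    away from both edges, which minimises spectral-leakage ambiguity when
    the oscillation is recovered by band-power integration.
    """

    band_label: str
    amplitude: float
    frequency: float | None = None
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.band_label not in BANDS_BY_LABEL:
            raise ValueError(f"unknown band {self.band_label!r}")
        if self.amplitude < 0:
            raise ValueError("oscillator amplitude must be >= 0")
        band = self.band
        if self.frequency is None:
            object.__setattr__(self, "frequency", band.geometric_centre)
        if not band.contains(self.frequency, strict=True):
            raise ValueError(
                f"frequency {self.frequency} Hz not strictly inside "
                f"{self.band_label} band [{band.f_lo}, {band.f_hi}] Hz"
            )

    @property
    def band(self) -> FrequencyBand:
        return BANDS_BY_LABEL[self.band_label]


@dataclass(frozen=True)
class ROISignalModel:
    """Injectable parameters of one ROI's temperature signal.

    Attributes
    ----------
    baseline_temp : trend value at t = 0, degC.
    phase_slopes : linear slope of the trend per phase label, degC/s.
        Unlisted labels get slope 0 (a plateau). The trend is continuous:
        each phase starts where the previous one ended.
    oscillators_pre / oscillators_post : sinusoids active during the
        baseline and recovery phases respectively.
    noise_sd : SD of i.i.d. Gaussian sensor noise, degC.
    """

    baseline_temp: float
    phase_slopes: Mapping[str, float] = field(default_factory=dict)
    oscillators_pre: tuple[BandOscillator, ...] = ()
    oscillators_post: tuple[BandOscillator, ...] = ()
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "oscillators_pre", tuple(self.oscillators_pre))
        object.__setattr__(self, "oscillators_post", tuple(self.oscillators_post))

    def trend_at(self, t_s: float, timeline: SessionTimeline) -> float:
        """Trend temperature at time t (closed form, used for ground truth)."""
        value = self.baseline_temp
        for p in timeline.phases:
            slope = self.phase_slopes.get(p.label, 0.0)
            if t_s >= p.end_s:
                value += slope * p.duration_s
            elif t_s > p.start_s:
                value += slope * (t_s - p.start_s)
                break
            else:
                break
        return value


def _trend_array(
    model: ROISignalModel, timeline: SessionTimeline, t: np.ndarray
) -> np.ndarray:
    # knots at phase boundaries; linear interpolation reproduces the
    # piecewise-linear trend exactly
    knots_t = [0.0]
    knots_v = [model.baseline_temp]
    for p in timeline.phases:
        slope = model.phase_slopes.get(p.label, 0.0)
        knots_t.append(p.end_s)
        knots_v.append(knots_v[-1] + slope * p.duration_s)
    return np.interp(t, knots_t, knots_v)


def synthesize_trace(
    model: ROISignalModel,
    timeline: SessionTimeline,
    fs: float = 10.0,
    seed: int | np.random.Generator | None = 0,
    label: str = "ROI",
) -> ROITrace:
    """Generate one ROI temperature trace.

    The trace has ``round(end_s * fs)`` samples. Pre-epoch oscillators run
    during the baseline phase, post-epoch oscillators during the recovery
    phase; each oscillator's phase is referenced to its epoch start. Output
    is deterministic for a fixed seed, and with ``noise_sd = 0`` and no
    oscillators the trace equals the piecewise-linear trend exactly.

    Raises
    ------
    ValueError
        If any oscillator violates the Nyquist condition fs > 2 f.
    """
    for osc in model.oscillators_pre + model.oscillators_post:
        if not fs > 2.0 * osc.frequency:
            raise ValueError(
                f"Nyquist violation: {osc.band_label} oscillator at "
                f"{osc.frequency} Hz needs fs > {2 * osc.frequency} Hz, got {fs}"
            )

    n = int(round(timeline.end_s * fs))
    t = np.arange(n) / fs
    values = _trend_array(model, timeline, t)

    for epoch, oscillators in (
        (timeline.baseline, model.oscillators_pre),
        (timeline.recovery, model.oscillators_post),
    ):
        if not oscillators:
            continue
        mask = (t >= epoch.start_s) & (t < epoch.end_s)
        tt = t[mask] - epoch.start_s
        for osc in oscillators:
            values[mask] += osc.amplitude * np.sin(
                2.0 * np.pi * osc.frequency * tt + osc.phase
            )

    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, model.noise_sd, size=n)

    np.clip(values, *TEMP_CLAMP, out=values)
    return ROITrace(label=label, values=values, fs=fs)
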