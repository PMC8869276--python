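"""Time- and frequency-domain features of ROI temperature traces.

Two feature families are computed per ROI:

* ``delta_t`` — the pre/post temperature change: the mean temperature over a
  10-s window at the end of the recording minus the mean over a 10-s window
  ending 10 s before the first exercise repetition.

* ``dpsd_<band>`` — the pre/post change in band-limited spectral power: the
  power spectral density (PSD) of the trace is estimated over the final
  5 minutes of the recording and over the 5 minutes preceding the first
  repetition, integrated over each of the five canonical vasomotion bands
  (metabolic, neurogenic, myogenic, respiratory, cardiac), and differenced
  post minus pre. Units are degC^2 (area under a degC^2/Hz density).

The PSD estimator is Welch's averaged periodogram: 150-s Hann-tapered
segments with 50% overlap, each segment linearly detrended, and each
segment's density rescaled so its integral over [0, fs/2] equals that
segment's detrended variance exactly (Parseval by construction rather than
in expectation). With 150-s segments the frequency resolution is
about 0.0067 Hz, coarser than the 0.003 Hz lower edge of the metabolic band;
that band is integrated from the first available nonzero grid point and
flagged as resolution-limited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BAND_LABELS, CANONICAL_BANDS, FrequencyBand
from .timeline import SessionTimeline
from .trace import ROITrace

#: The four regions of interest of the standard protocol.
DEFAULT_ROI_LABELS = ("Exercised Leg", "Nonexercised Leg", "Nose Tip", "Corrugator")

#: Feature columns of a feature table, in canonical order.
FEATURE_COLUMNS = ("delta_t",) + tuple(f"dpsd_{b}" for b in BAND_LABELS)

#: Duration of the ΔT averaging windows, seconds.
DT_WINDOW_S = 10.0
#: Gap between the baseline ΔT window and the first repetition, seconds.
DT_BASELINE_GAP_S = 10.0
#: Duration of the PSD windows, seconds (5 minutes).
PSD_WINDOW_S = 300.0


@dataclass(frozen=True)
class AnalysisWindows:
    """The four analysis windows anchored to a session timeline (seconds)."""

    dt_baseline: tuple[float, float]
    dt_final: tuple[float, float]
    psd_pre: tuple[float, float]
    psd_post: tuple[float, float]

    @classmethod
    def from_timeline(cls, timeline: SessionTimeline) -> "AnalysisWindows":
        t1 = timeline.first_rep_s
        t_end = timeline.end_s
        return cls(
            dt_baseline=(t1 - DT_BASELINE_GAP_S - DT_WINDOW_S, t1 - DT_BASELINE_GAP_S),
            dt_final=(t_end - DT_WINDOW_S, t_end),
            psd_pre=(t1 - PSD_WINDOW_S, t1),
            psd_post=(t_end - PSD_WINDOW_S, t_end),
        )

    def infeasible(self, trace: ROITrace) -> list[str]:
        """Names of windows that do not fit inside the trace."""
        bad = []
        for name in ("dt_baseline", "dt_final", "psd_pre", "psd_post"):
            start, end = getattr(self, name)
            try:
                trace.window_slice(start, end)
            except ValueError:
                bad.append(name)
        return bad

    def epoch_violations(self, timeline: SessionTimeline) -> list[str]:
        """Windows that spill out of their anchoring phase.

        The pre-exercise windows must lie inside the baseline phase and the
        post-exercise spectral window inside the recovery phase (a 5-min
        spectral window needs a >= 5-min epoch); otherwise the window would
        mix exercise-phase motion artefacts into a resting-state estimate.
        """
        bad = []
        baseline = timeline.baseline
        recovery = timeline.recovery
        if self.dt_baseline[0] < baseline.start_s:
            bad.append("dt_baseline")
        if self.psd_pre[0] < baseline.start_s:
            bad.append("psd_pre")
        if self.psd_post[0] < recovery.start_s:
            bad.append("psd_post")
        return bad


def delta_t_roi(trace: ROITrace, timeline: SessionTimeline) -> float:
    """Pre/post temperature change ΔT for one ROI, degC.

    Mean over the final 10-s window minus mean over the 10-s window ending
    10 s before the first repetition. Each window holds round(10 * fs)
    samples. Raises ValueError naming the window that falls outside the
    trace.
    """
    win = AnalysisWindows.from_timeline(timeline)
    for name in ("dt_baseline", "dt_final"):
        start, end = getattr(win, name)
        try:
            trace.window_slice(start, end)
        except ValueError as exc:
            raise ValueError(f"ΔT window {name!r} out of range: {exc}") from exc
    pre = trace.window_values(*win.dt_baseline).mean()
    post = trace.window_values(*win.dt_final).mean()
    return float(post - pre)


@dataclass(frozen=True)
class PsdSettings:
    """Welch estimator settings (recorded verbatim in every estimate)."""

    segment_s: float = 150.0
    overlap: float = 0.5
    window: str = "hann"
    detrend: str = "linear"

    def nperseg(self, fs: float) -> int:
        return int(round(self.segment_s * fs))

    def noverlap(self, fs: float) -> int:
        return int(round(self.segment_s * fs * self.overlap))


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided PSD on a regular frequency grid."""

    frequencies: np.ndarray  # Hz
    density: np.ndarray  # degC^2 / Hz
    fs: float
    settings: PsdSettings

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("PSD density must be non-negative")

    @property
    def df(self) -> float:
        """Frequency grid resolution, Hz."""
        return float(self.frequencies[1] - self.frequencies[0])

    def total_power(self) -> float:
        """Trapezoidal integral of the density over [0, fs/2], degC^2."""
        return float(np.trapezoid(self.density, self.frequencies))


def estimate_psd(
    segment: np.ndarray | ROITrace,
    fs: float | None = None,
    settings: PsdSettings | None = None,
    expected_duration_s: float = PSD_WINDOW_S,
) -> PSDEstimate:
    """Welch PSD of one analysis segment.

    The segment must be exactly ``expected_duration_s`` long (default 5 min;
    3000 samples at 10 Hz) — no silent padding or truncation.
    """
    if isinstance(segment, ROITrace):
        fs = segment.fs
        segment = segment.values
    if fs is None:
        raise ValueError("fs is required when segment is a bare array")
    settings = settings or PsdSettings()
    segment = np.asarray(segment, dtype=np.float64)
    n_expected = int(round(expected_duration_s * fs))
    if segment.size != n_expected:
        raise ValueError(
            f"segment has {segment.size} samples; expected {n_expected} "
            f"({expected_duration_s} s at {fs} Hz) — no silent padding"
        )
    nperseg = settings.nperseg(fs)
    step = nperseg - settings.noverlap(fs)
    if nperseg > segment.size or step < 1:
        raise ValueError(
            f"Welch segment of {nperseg} samples does not fit a "
            f"{segment.size}-sample window at overlap {settings.overlap}"
        )
    # Welch average with an exact per-segment Parseval normalisation: each
    # tapered periodogram is rescaled so its integral equals that segment's
    # detrended sample variance. The conventional taper-power normalisation
    # preserves variance only in expectation; rescaling makes the integral
    # of the density match the power the estimator actually saw, so band
    # powers can never exceed the signal's variance budget.
    freqs = None
    densities = []
    for i in range(0, segment.size - nperseg + 1, step):
        seg = segment[i : i + nperseg]
        if settings.detrend in ("linear", "constant"):
            seg = sps.detrend(seg, type=settings.detrend)
            target = float(np.var(seg))
        elif settings.detrend in ("none", None):
            target = float(np.mean(seg**2))
        else:
            raise ValueError(f"unknown detrend mode {settings.detrend!r}")
        freqs, d = sps.periodogram(
            seg, fs=fs, window=settings.window, detrend=False, scaling="density"
        )
        integral = float(np.trapezoid(d, freqs))
        if integral > 0.0:
            d = d * (target / integral)
        densities.append(d)
    density = np.mean(densities, axis=0)
    return PSDEstimate(frequencies=freqs, density=density, fs=fs, settings=settings)


def band_is_resolution_limited(psd: PSDEstimate, band: FrequencyBand) -> bool:
    """True when the band's lower edge falls below the first nonzero grid point."""
    return band.f_lo < psd.frequencies[1]


def band_power(psd: PSDEstimate, band: FrequencyBand) -> float:
    """Area under the PSD over [f_lo, f_hi], degC^2.

    Trapezoidal integration with linear interpolation of the density at band
    edges that fall between grid points, which makes the integral exactly
    additive over any partition of the band. A lower edge below the first
    nonzero grid point (metabolic band at the default settings) is moved up
    to that grid point; use :func:`band_is_resolution_limited` to detect
    this.
    """
    nyquist = psd.fs / 2.0
    if band.f_hi > nyquist:
        raise ValueError(
            f"band {band.label!r} upper edge {band.f_hi} Hz exceeds the "
            f"Nyquist frequency {nyquist} Hz"
        )
    f = psd.frequencies
    d = psd.density
    f_lo = max(band.f_lo, float(f[1]))  # resolution floor: skip the DC bin
    f_hi = band.f_hi
    if f_hi <= f_lo:
        return 0.0
    grid = f[(f > f_lo) & (f < f_hi)]
    xs = np.concatenate(([f_lo], grid, [f_hi]))
    ys = np.interp(xs, f, d)
    return float(np.trapezoid(ys, xs))


@dataclass(frozen=True)
class DeltaFeatures:
    """Per-ROI pre/post feature changes.

    ``delta_psd[b] == band_power_post[b] - band_power_pre[b]`` exactly;
    ``flags`` lists data-quality annotations such as resolution-limited
    bands.
    """

    roi_label: str
    delta_t: float | None
    band_power_pre: dict[str, float]
    band_power_post: dict[str, float]
    delta_psd: dict[str, float]
    flags: tuple[str, ...] = ()


def delta_psd(
    trace: ROITrace,
    timeline: SessionTimeline,
    bands: Sequence[FrequencyBand] = CANONICAL_BANDS,
    settings: PsdSettings | None = None,
) -> DeltaFeatures:
    """Per-band spectral-power change (post minus pre) for one ROI.

    PSDs are estimated over the 5-min window before the first repetition and
    the final 5-min window; each band's area under the curve is differenced.
    Raises ValueError when either window does not fit the trace.
    """
    win = AnalysisWindows.from_timeline(timeline)
    bad = sorted(
        name
        for name in ("psd_pre", "psd_post")
        if name in win.infeasible(trace) or name in win.epoch_violations(timeline)
    )
    if bad:
        raise ValueError(
            f"PSD window(s) {bad} infeasible for trace {trace.label!r} "
            f"(need {PSD_WINDOW_S} s inside the trace)"
        )
    psd_pre = estimate_psd(trace.window_values(*win.psd_pre), trace.fs, settings)
    psd_post = estimate_psd(trace.window_values(*win.psd_post), trace.fs, settings)

    pre = {b.label: band_power(psd_pre, b) for b in bands}
    post = {b.label: band_power(psd_post, b) for b in bands}
    delta = {lbl: post[lbl] - pre[lbl] for lbl in pre}
    flags = tuple(
        f"resolution_limited:{b.label}"
        for b in bands
        if band_is_resolution_limited(psd_pre, b)
    )
    return DeltaFeatures(
        roi_label=trace.label,
        delta_t=None,
        band_power_pre=pre,
        band_power_post=post,
        delta_psd=delta,
        flags=flags,
    )


def compute_delta_features(
    trace: ROITrace,
    timeline: SessionTimeline,
    bands: Sequence[FrequencyBand] = CANONICAL_BANDS,
    settings: PsdSettings | None = None,
) -> DeltaFeatures:
    """Both feature families (ΔT and per-band ΔPSD) for one ROI."""
    freq = delta_psd(trace, timeline, bands, settings)
    dt = delta_t_roi(trace, timeline)
    return DeltaFeatures(
        roi_label=trace.label,
        delta_t=dt,
        band_power_pre=freq.band_power_pre,
        band_power_post=freq.band_power_post,
        delta_psd=freq.delta_psd,
        flags=freq.flags,
    )


@dataclass(frozen=True)
class FeatureTable:
    """Subject x ROI feature table plus per-subject exertion ratings.

    ``data`` is tidy: one row per subject x ROI with columns
    subject_id, roi, delta_t, dpsd_<band>..., rpe, flags.
    ``exclusions`` records subjects dropped with the reason — exclusion is
    never silent.
    """

    data: pd.DataFrame
    exclusions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        dup = self.data.duplicated(subset=["subject_id", "roi"])
        if dup.any():
            pairs = self.data.loc[dup, ["subject_id", "roi"]].values.tolist()
            raise ValueError(f"duplicate subject x ROI rows: {pairs}")


def compute_feature_table(
    traces: Mapping[str, Mapping[str, ROITrace]],
    timelines: Mapping[str, SessionTimeline] | SessionTimeline,
    rpe: Mapping[str, int],
    bands: Sequence[FrequencyBand] = CANONICAL_BANDS,
    settings: PsdSettings | None = None,
) -> FeatureTable:
    """Assemble the subject x ROI feature table.

    Parameters
    ----------
    traces
        subject_id -> ROI label -> trace.
    timelines
        One timeline per subject, or a single shared timeline.
    rpe
        subject_id -> perceived-exertion rating (integer 1-10).

    Subjects whose traces cannot accommodate the analysis windows are
    excluded and listed in ``FeatureTable.exclusions`` with the reason.
    """
    rows = []
    exclusions: list[tuple[str, str]] = []
    for subject_id in traces:
        tl = timelines if isinstance(timelines, SessionTimeline) else timelines[subject_id]
        win = AnalysisWindows.from_timeline(tl)
        epoch_bad = win.epoch_violations(tl)
        subject_rows = []
        reason = None
        for roi_label, trace in traces[subject_id].items():
            bad = sorted(set(win.infeasible(trace)) | set(epoch_bad))
            if bad:
                reason = f"ROI {roi_label!r}: infeasible window(s) {bad}"
                break
            feats = compute_delta_features(trace, tl, bands, settings)
            row = {
                "subject_id": subject_id,
                "roi": roi_label,
                "delta_t": feats.delta_t,
                **{f"dpsd_{lbl}": v for lbl, v in feats.delta_psd.items()},
                "rpe": int(rpe[subject_id]),
                "flags": ";".join(feats.flags),
            }
            subject_rows.append(row)
        if reason is not None:
            exclusions.append((subject_id, reason))
        else:
            rows.extend(subject_rows)
    columns = ["subject_id", "roi", *FEATURE_COLUMNS, "rpe", "flags"]
    data = pd.DataFrame(rows, columns=columns)
    return FeatureTable(data=data, exclusions=tuple(exclusions))
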