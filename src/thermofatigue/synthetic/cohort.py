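"""Cohort-level simulation: per-subject traces, exertion ratings, ground truth.

Subjects are drawn from between-subject distributions of the injectable
signal parameters. The generator records, per subject and ROI, the *injected*
feature values (the temperature change realised by the trend, and the band
power change (A_post^2 - A_pre^2)/2 realised by the oscillators), so that the
extraction chain can be validated against exact ground truth.

The perceived-exertion rating (RPE, integer 1-10) is a noisy linear readout
of chosen true features, truncated to [1, 10] and rounded — the standard
latent-variable construction in which a target Pearson correlation rho maps
to slope b = rho * sd(RPE) / sd(feature) and residual SD
sd(RPE) * sqrt(1 - rho^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ..bands import BAND_LABELS
from ..features import DEFAULT_ROI_LABELS, FEATURE_COLUMNS
from ..timeline import SessionTimeline, make_default_timeline
from ..trace import ROITrace
from .signal import DEFAULT_NOISE_SD, BandOscillator, ROISignalModel, synthesize_trace


@dataclass(frozen=True)
class ROICohortParams:
    """Between-subject distribution of one ROI's signal parameters.

    ``amp_pre`` / ``amp_post`` map band label -> (mean, sd) of the oscillator
    amplitude (degC) in the baseline and recovery epochs; draws are clipped
    at zero. ``delta_t`` is the injected pre/post temperature change, realised
    as a linear trend spread over the exercise sets.
    """

    baseline_temp_mean: float
    baseline_temp_sd: float = 0.3
    delta_t_mean: float = 0.0
    delta_t_sd: float = 0.3
    amp_pre: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    amp_post: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD


@dataclass(frozen=True)
class RpeCoupling:
    """RPE as a noisy linear readout of true features.

    ``slopes`` maps (roi_label, feature_name) -> slope. The latent rating is
    intercept + sum(slope * true_feature) + N(0, residual_sd), then clipped
    to [1, 10] and rounded to an integer.
    """

    intercept: float
    slopes: Mapping[tuple[str, str], float] = field(default_factory=dict)
    residual_sd: float = 0.0

    @classmethod
    def for_target_r(
        cls,
        target_r: float,
        roi: str,
        feature: str,
        feature_mean: float,
        feature_sd: float,
        rpe_mean: float = 6.0,
        rpe_sd: float = 1.5,
    ) -> "RpeCoupling":
        """Coupling whose latent rating has Pearson correlation ``target_r``
        with the named true feature (before rounding/clipping)."""
        if not -1.0 < target_r < 1.0 or target_r == 0.0:
            raise ValueError("target_r must be in (-1, 1) and nonzero")
        if feature_sd <= 0:
            raise ValueError("feature_sd must be positive")
        slope = target_r * rpe_sd / feature_sd
        residual_sd = rpe_sd * float(np.sqrt(1.0 - target_r**2))
        intercept = rpe_mean - slope * feature_mean
        return cls(intercept=intercept, slopes={(roi, feature): slope},
                   residual_sd=residual_sd)

    def sample(
        self,
        true_features: Mapping[tuple[str, str], float],
        rng: np.random.Generator,
    ) -> int:
        """One subject's rating from their true feature values."""
        latent = self.intercept
        for key, slope in self.slopes.items():
            latent += slope * true_features[key]
        if self.residual_sd > 0:
            latent += rng.normal(0.0, self.residual_sd)
        return int(round(float(np.clip(latent, 1.0, 10.0))))


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort."""

    n_subjects: int
    roi_params: Mapping[str, ROICohortParams]
    rpe_coupling: RpeCoupling | None = None
    fs: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not self.roi_params:
            raise ValueError("roi_params must name at least one ROI")


@dataclass(frozen=True)
class CohortData:
    """Generator output: traces, ratings, and exact injected ground truth."""

    traces: dict[str, dict[str, ROITrace]]  # subject -> roi -> trace
    rpe: dict[str, int]
    truth: pd.DataFrame  # subject_id, roi, delta_t, dpsd_<band>...
    timeline: SessionTimeline


def _draw_model(
    params: ROICohortParams,
    timeline: SessionTimeline,
    rng: np.random.Generator,
) -> tuple[ROISignalModel, dict[str, float]]:
    """One subject's signal model for one ROI, plus its true feature values."""
    baseline = rng.normal(params.baseline_temp_mean, params.baseline_temp_sd)
    delta_t = rng.normal(params.delta_t_mean, params.delta_t_sd)
    total_set_s = sum(p.duration_s for p in timeline.phases_labelled("set"))
    slopes = {"set": delta_t / total_set_s}

    def draw_amps(dist: Mapping[str, tuple[float, float]]) -> dict[str, float]:
        return {
            band: max(0.0, rng.normal(mean, sd)) for band, (mean, sd) in dist.items()
        }

    amps_pre = draw_amps(params.amp_pre)
    amps_post = draw_amps(params.amp_post)
    model = ROISignalModel(
        baseline_temp=baseline,
        phase_slopes=slopes,
        oscillators_pre=tuple(
            BandOscillator(band, amp) for band, amp in amps_pre.items() if amp > 0
        ),
        oscillators_post=tuple(
            BandOscillator(band, amp) for band, amp in amps_post.items() if amp > 0
        ),
        noise_sd=params.noise_sd,
    )
    truth = {"delta_t": delta_t}
    for band in BAND_LABELS:
        a_pre = amps_pre.get(band, 0.0)
        a_post = amps_post.get(band, 0.0)
        truth[f"dpsd_{band}"] = (a_post**2 - a_pre**2) / 2.0
    return model, truth


def synthesize_cohort(spec: CohortSpec, timeline: SessionTimeline) -> CohortData:
    """Generate a full cohort; bit-reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    traces: dict[str, dict[str, ROITrace]] = {}
    truth_rows = []
    truth_by_subject: dict[str, dict[tuple[str, str], float]] = {}

    for i in range(spec.n_subjects):
        subject_id = f"S{i + 1:02d}"
        traces[subject_id] = {}
        truth_by_subject[subject_id] = {}
        for roi_label, params in spec.roi_params.items():
            model, truth = _draw_model(params, timeline, rng)
            trace = synthesize_trace(
                model, timeline, fs=spec.fs, seed=rng, label=roi_label
            )
            traces[subject_id][roi_label] = trace
            truth_rows.append({"subject_id": subject_id, "roi": roi_label, **truth})
            for feat, val in truth.items():
                truth_by_subject[subject_id][(roi_label, feat)] = val

    rpe: dict[str, int] = {}
    coupling = spec.rpe_coupling or RpeCoupling(intercept=6.0)
    for subject_id in traces:
        rpe[subject_id] = coupling.sample(truth_by_subject[subject_id], rng)

    truth = pd.DataFrame(
        truth_rows, columns=["subject_id", "roi", *FEATURE_COLUMNS]
    )
    return CohortData(traces=traces, rpe=rpe, truth=truth, timeline=timeline)


def null_feature_table(
    n_subjects: int,
    rng: np.random.Generator | int | None = 0,
    rois: tuple[str, ...] = DEFAULT_ROI_LABELS,
    subject_sd: float = 1.0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Feature table with exchangeable ROIs and no RPE coupling.

    Every feature value is subject_effect + independent noise, identically
    distributed across ROIs (compound symmetry, so sphericity holds and the
    omnibus null is true). Used for type-I-error studies of the statistics
    layer.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        subject_effects = {f: rng.normal(0.0, subject_sd) for f in FEATURE_COLUMNS}
        subj_rpe = int(rng.integers(1, 11))
        for roi in rois:
            row = {"subject_id": sid, "roi": roi, "rpe": subj_rpe}
            for f in FEATURE_COLUMNS:
                row[f] = subject_effects[f] + rng.normal(0.0, noise_sd)
            rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "roi", *FEATURE_COLUMNS, "rpe"])


def study_cohort_spec(n_subjects: int = 8, seed: int = 0) -> CohortSpec:
    """The default study-conditions scenario.

    Eight subjects, four ROIs. The exercised leg warms (about +1.5 degC) and
    gains myogenic-band power; the nose tip warms mildly and both facial
    ROIs gain neurogenic-band power while losing myogenic power; the
    non-exercised leg and corrugator cool slightly. RPE is coupled
    negatively (rho = -0.8) to the exercised leg's temperature change.
    """
    flat = {band: (0.02, 0.005) for band in BAND_LABELS}

    def roi(base, dt_mean, dt_sd, pre_over=None, post_over=None, **kw):
        pre = dict(flat)
        post = dict(flat)
        pre.update(pre_over or {})
        post.update(post_over or {})
        return ROICohortParams(
            baseline_temp_mean=base,
            delta_t_mean=dt_mean,
            delta_t_sd=dt_sd,
            amp_pre=pre,
            amp_post=post,
            **kw,
        )

    roi_params = {
        "Exercised Leg": roi(
            31.0, 1.5, 0.5,
            pre_over={"myogenic": (0.03, 0.005)},
            post_over={"myogenic": (0.10, 0.01)},
        ),
        "Nonexercised Leg": roi(
            31.0, -0.2, 0.3,
            pre_over={"myogenic": (0.03, 0.005)},
            post_over={"myogenic": (0.04, 0.005)},
        ),
        "Nose Tip": roi(
            33.0, 0.4, 0.3,
            pre_over={"neurogenic": (0.03, 0.005), "myogenic": (0.05, 0.005)},
            post_over={"neurogenic": (0.08, 0.01), "myogenic": (0.03, 0.005)},
        ),
        "Corrugator": roi(
            33.5, -0.3, 0.3,
            pre_over={"neurogenic": (0.03, 0.005), "myogenic": (0.05, 0.005)},
            post_over={"neurogenic": (0.07, 0.01), "myogenic": (0.03, 0.005)},
        ),
    }
    coupling = RpeCoupling.for_target_r(
        target_r=-0.8,
        roi="Exercised Leg",
        feature="delta_t",
        feature_mean=1.5,
        feature_sd=0.5,
        rpe_mean=7.0,
        rpe_sd=1.5,
    )
    return CohortSpec(
        n_subjects=n_subjects, roi_params=roi_params, rpe_coupling=coupling, seed=seed
    )


def study_protocol_timeline() -> SessionTimeline:
    """Default protocol timeline: 5-min baseline, three sets to exhaustion
    (60/50/40 s) with 3-min rests, 5-min recovery."""
    return make_default_timeline([60.0, 50.0, 40.0])
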