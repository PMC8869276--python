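"""Inference layer: normality diagnostics, repeated-measures ANOVA with
sphericity correction, unadjusted pairwise post hocs, and feature-RPE
correlations.

The design is one within-subject factor (ROI, k = 4 levels) per feature.
The omnibus test is the classical repeated-measures ANOVA
F = MS_conditions / MS_error with subject blocking; because sphericity of
the condition covariance cannot be assumed, degrees of freedom are
multiplied by the Greenhouse-Geisser epsilon estimated from the sample
covariance of condition scores (Huynh-Feldt available as an option).
Post hoc comparisons follow the Fisher LSD convention for repeated
measures: all pairwise paired t-tests, two-sided, unadjusted, each with its
own pair error term. Feature-RPE association uses Pearson's r with the
two-sided p from the t transform on n - 2 degrees of freedom, with no
multiplicity adjustment across the feature x ROI matrix.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .features import FEATURE_COLUMNS

ALPHA = 0.05


def _stars(p: float, levels: Sequence[float] = (0.05, 0.01, 0.001)) -> str:
    return "*" * sum(p < lvl for lvl in levels)


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p).

    A reported diagnostic, not an automatic gate: non-normal features stay
    in the parametric pipeline and are flagged in the report instead.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 3 or values.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0.0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    res = sst.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def _condition_matrix(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Subjects x ROI wide matrix; errors on an incomplete crossing."""
    wide = table.pivot(index="subject_id", columns="roi", values=feature)
    if wide.isna().any().any():
        missing = [
            (s, r) for (s, r) in zip(*np.nonzero(wide.isna().values))
        ]
        cells = [
            f"({wide.index[s]}, {wide.columns[r]})" for s, r in missing
        ]
        raise ValueError(f"incomplete subject x ROI crossing; missing cells: {cells}")
    return wide


def greenhouse_geisser_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of the
    n x k condition-score matrix. Bounded in [1/(k-1), 1]."""
    scores = np.asarray(scores, dtype=np.float64)
    k = scores.shape[1]
    S = np.cov(scores, rowvar=False, ddof=1)
    mean_diag = np.trace(S) / k
    grand_mean = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand_mean)) ** 2
    den = (k - 1) * (
        np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * grand_mean**2
    )
    if den <= 0:
        return 1.0
    eps = num / den
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def huynh_feldt_epsilon(scores: np.ndarray) -> float:
    """Huynh-Feldt epsilon (less conservative than Greenhouse-Geisser)."""
    n, k = np.asarray(scores).shape
    eps_gg = greenhouse_geisser_epsilon(scores)
    num = n * (k - 1) * eps_gg - 2
    den = (k - 1) * (n - 1 - (k - 1) * eps_gg)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


@dataclass(frozen=True)
class AnovaResult:
    feature: str
    f: float
    df1: float  # corrected
    df2: float  # corrected
    epsilon: float
    p: float
    correction: str
    df1_uncorrected: int
    df2_uncorrected: int
    p_uncorrected: float
    n_subjects: int
    n_conditions: int


def rm_anova(
    table: pd.DataFrame, feature: str, correction: str = "gg"
) -> AnovaResult:
    """One-way repeated-measures ANOVA across ROIs for one feature.

    ``correction`` is "gg" (Greenhouse-Geisser, default), "hf" (Huynh-Feldt)
    or "none". Corrected and uncorrected results are both reported.
    """
    wide = _condition_matrix(table, feature)
    scores = wide.to_numpy(dtype=np.float64)
    n, k = scores.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs n >= 2 subjects")

    grand = scores.mean()
    cond_means = scores.mean(axis=0)
    subj_means = scores.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((scores - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj

    df1u, df2u = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1u
    ms_err = ss_err / df2u
    f = 0.0 if ms_cond == 0.0 else float(ms_cond / max(ms_err, np.finfo(float).tiny))

    if correction == "gg":
        eps = greenhouse_geisser_epsilon(scores)
    elif correction == "hf":
        eps = huynh_feldt_epsilon(scores)
    elif correction == "none":
        eps = 1.0
    else:
        raise ValueError(f"unknown correction {correction!r}")

    df1, df2 = eps * df1u, eps * df2u
    p = float(sst.f.sf(f, df1, df2))
    p_unc = float(sst.f.sf(f, df1u, df2u))
    return AnovaResult(
        feature=feature, f=f, df1=float(df1), df2=float(df2), epsilon=float(eps),
        p=p, correction=correction, df1_uncorrected=df1u, df2_uncorrected=df2u,
        p_uncorrected=p_unc, n_subjects=n, n_conditions=k,
    )


@dataclass(frozen=True)
class PairwiseResult:
    roi_a: str
    roi_b: str
    mean_diff: float  # mean(a) - mean(b)
    t: float
    p: float
    stars: str


def lsd_posthoc(table: pd.DataFrame, feature: str) -> tuple[PairwiseResult, ...]:
    """All pairwise paired t-tests, two-sided, unadjusted (Fisher LSD).

    Each pair uses its own error term (the SD of the within-subject
    differences for that pair), the common software convention.
    """
    wide = _condition_matrix(table, feature)
    results = []
    for roi_a, roi_b in combinations(wide.columns, 2):
        a = wide[roi_a].to_numpy(dtype=np.float64)
        b = wide[roi_b].to_numpy(dtype=np.float64)
        diff = a - b
        if np.ptp(diff) == 0.0:
            t, p = 0.0, 1.0
        else:
            res = sst.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
        results.append(
            PairwiseResult(
                roi_a=str(roi_a), roi_b=str(roi_b),
                mean_diff=float(diff.mean()), t=t, p=p, stars=_stars(p),
            )
        )
    return tuple(results)


@dataclass(frozen=True)
class CorrelationCell:
    feature: str
    roi: str
    r: float  # NaN when degenerate
    p: float
    n: int
    stars: str
    degenerate: bool = False


def correlate_with_rpe(
    table: pd.DataFrame, features: Sequence[str] = FEATURE_COLUMNS
) -> tuple[CorrelationCell, ...]:
    """Pearson correlation of each (feature, ROI) vector with per-subject RPE.

    One RPE per subject; zero-variance inputs give a flagged NaN cell rather
    than an error. Stars: * p < 0.05, ** p < 0.01 (no multiplicity
    adjustment across the matrix).
    """
    cells = []
    for roi, grp in table.groupby("roi", sort=False):
        grp = grp.sort_values("subject_id")
        rpe = grp["rpe"].to_numpy(dtype=np.float64)
        for feature in features:
            x = grp[feature].to_numpy(dtype=np.float64)
            n = x.size
            if n < 3:
                raise ValueError("Pearson correlation needs n >= 3 subjects")
            if np.ptp(x) == 0.0 or np.ptp(rpe) == 0.0:
                cells.append(
                    CorrelationCell(feature, str(roi), float("nan"), float("nan"),
                                    n, "", degenerate=True)
                )
                continue
            res = sst.pearsonr(x, rpe)
            p = float(res.pvalue)
            cells.append(
                CorrelationCell(feature, str(roi), float(res.statistic), p, n,
                                _stars(p, (0.05, 0.01)))
            )
    return tuple(cells)


def boxplot_summary(values: np.ndarray) -> dict[str, float]:
    """Median, quartiles and range, for box-and-whisker style summaries."""
    values = np.asarray(values, dtype=np.float64)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()), "q1": float(q1), "median": float(med),
        "q3": float(q3), "max": float(values.max()),
    }


@dataclass(frozen=True)
class StatsReport:
    """Machine-readable inference report for one feature table."""

    anova: tuple[AnovaResult, ...]
    posthoc: Mapping[str, tuple[PairwiseResult, ...]]
    correlations: tuple[CorrelationCell, ...]
    normality: Mapping[str, Mapping[str, tuple[float, float]]]
    box_summaries: Mapping[str, Mapping[str, dict[str, float]]]
    alpha: float
    settings: Mapping[str, object]
    warnings: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "settings": dict(self.settings),
            "warnings": list(self.warnings),
            "anova": [asdict(a) for a in self.anova],
            "posthoc": {
                feat: [asdict(p) for p in pairs]
                for feat, pairs in self.posthoc.items()
            },
            "correlations": [asdict(c) for c in self.correlations],
            "normality": {
                feat: {roi: list(wp) for roi, wp in rois.items()}
                for feat, rois in self.normality.items()
            },
            "box_summaries": {
                feat: {roi: dict(s) for roi, s in rois.items()}
                for feat, rois in self.box_summaries.items()
            },
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True,
                          allow_nan=True)

    def to_markdown(self) -> str:
        lines = ["# Inference report", ""]
        lines.append("## Repeated-measures ANOVA (across ROIs)")
        lines.append("")
        lines.append("| feature | F | df1 | df2 | epsilon | p | sig |")
        lines.append("|---|---|---|---|---|---|---|")
        for a in self.anova:
            sig = "yes" if a.p < self.alpha else "no"
            lines.append(
                f"| {a.feature} | {a.f:.3f} | {a.df1:.2f} | {a.df2:.2f} "
                f"| {a.epsilon:.3f} | {a.p:.4f} | {sig} |"
            )
        lines.append("")
        lines.append("## Pairwise comparisons (unadjusted paired t)")
        for feat, pairs in self.posthoc.items():
            lines.append("")
            lines.append(f"### {feat}")
            lines.append("")
            lines.append("| pair | mean diff | t | p | |")
            lines.append("|---|---|---|---|---|")
            for pr in pairs:
                lines.append(
                    f"| {pr.roi_a} vs {pr.roi_b} | {pr.mean_diff:.4g} "
                    f"| {pr.t:.3f} | {pr.p:.4f} | {pr.stars} |"
                )
        lines.append("")
        lines.append("## Pearson correlations with RPE")
        lines.append("")
        rois = sorted({c.roi for c in self.correlations})
        lines.append("| feature | " + " | ".join(rois) + " |")
        lines.append("|" + "---|" * (len(rois) + 1))
        by_key = {(c.feature, c.roi): c for c in self.correlations}
        feats = list(dict.fromkeys(c.feature for c in self.correlations))
        for feat in feats:
            cells = []
            for roi in rois:
                c = by_key.get((feat, roi))
                cells.append("-" if c is None or c.degenerate
                             else f"{c.r:.2f}{c.stars}")
            lines.append(f"| {feat} | " + " | ".join(cells) + " |")
        lines.append("")
        lines.append(
            "Correlation p-values are unadjusted for the multiplicity of the "
            "feature x ROI matrix."
        )
        return "\n".join(lines) + "\n"


def build_report(
    table: pd.DataFrame,
    features: Sequence[str] = FEATURE_COLUMNS,
    correction: str = "gg",
    alpha: float = ALPHA,
) -> StatsReport:
    """Run the full inference layer on a tidy feature table."""
    warnings: list[str] = []
    anova = []
    posthoc = {}
    normality: dict[str, dict[str, tuple[float, float]]] = {}
    box: dict[str, dict[str, dict[str, float]]] = {}

    for feature in features:
        anova.append(rm_anova(table, feature, correction=correction))
        posthoc[feature] = lsd_posthoc(table, feature)
        normality[feature] = {}
        box[feature] = {}
        for roi, grp in table.groupby("roi", sort=False):
            vals = grp[feature].to_numpy(dtype=np.float64)
            box[feature][str(roi)] = boxplot_summary(vals)
            try:
                w, p = shapiro_wilk(vals)
            except ValueError as exc:
                warnings.append(f"normality check skipped for {feature}/{roi}: {exc}")
                continue
            normality[feature][str(roi)] = (w, p)
            if p < alpha:
                warnings.append(
                    f"normality questionable for {feature}/{roi} "
                    f"(Shapiro-Wilk p = {p:.3g}); parametric tests retained"
                )

    correlations = correlate_with_rpe(table, features)
    for c in correlations:
        if c.degenerate:
            warnings.append(f"degenerate correlation cell: {c.feature}/{c.roi}")

    return StatsReport(
        anova=tuple(anova),
        posthoc=posthoc,
        correlations=correlations,
        normality=normality,
        box_summaries=box,
        alpha=alpha,
        settings={
            "correction": correction,
            "posthoc": "pairwise paired t, per-pair error term, unadjusted",
            "correlation": "Pearson r, two-sided t transform, unadjusted",
        },
        warnings=tuple(warnings),
    )
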