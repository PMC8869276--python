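"""End-to-end orchestration: simulate -> features -> stats, with provenance.

A run is driven by a single YAML/JSON configuration document. In synthetic
mode the cohort generator produces traces, ratings and ground truth under a
mandatory seed; in real mode the run starts from a traces CSV written by the
extraction stage. Every stage writes its outputs into the run directory and
the manifest records a config hash, per-file checksums and all collected
warnings, so re-running an identical configuration yields identical
checksums and silent data exclusion is impossible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BAND_LABELS
from .features import AnalysisWindows, PsdSettings, compute_feature_table
from .stats import build_report
from .synthetic.cohort import study_cohort_spec, synthesize_cohort
from .timeline import SessionTimeline, make_default_timeline
from .trace import ROITrace

KNOWN_SCENARIOS = ("study_default",)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class Violation:
    path: str  # JSON-path locator into the config document
    message: str


def _default_config() -> dict:
    return {
        "mode": "synthetic",
        "seed": None,
        "scenario": {"name": "study_default", "n_subjects": 8},
        "timeline": {
            "set_durations_s": [60.0, 50.0, 40.0],
            "baseline_s": 300.0,
            "rest_s": 180.0,
            "recovery_s": 300.0,
        },
        "bands": list(BAND_LABELS),
        "psd": {"segment_s": 150.0, "overlap": 0.5, "window": "hann",
                "detrend": "linear"},
        "stats": {"correction": "gg", "alpha": 0.05, "rpe_agg": "last"},
        "inputs": {},  # real mode: traces_csv, timeline_file, rpe_csv
    }


def merge_config(user: Mapping[str, Any] | None) -> dict:
    """Defaults overlaid with the user document (one level of nesting)."""
    cfg = _default_config()
    for key, val in (user or {}).items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    if isinstance(cfg.get("scenario"), str):
        cfg["scenario"] = {"name": cfg["scenario"]}
    return cfg


def validate_config(doc: Mapping[str, Any]) -> list[Violation]:
    """All schema violations of a (merged) config document, never first-only."""
    cfg = merge_config(doc)
    v: list[Violation] = []

    mode = cfg.get("mode")
    if mode not in ("synthetic", "real"):
        v.append(Violation("mode", f"must be 'synthetic' or 'real', got {mode!r}"))

    if mode == "synthetic":
        seed = cfg.get("seed")
        if not isinstance(seed, int):
            v.append(Violation("seed", "an integer seed is mandatory in synthetic mode"))
        scen = cfg.get("scenario") or {}
        name = scen.get("name")
        if name not in KNOWN_SCENARIOS:
            v.append(Violation("scenario.name",
                               f"unknown scenario {name!r}; known: {KNOWN_SCENARIOS}"))
        n = scen.get("n_subjects", 8)
        if not (isinstance(n, int) and n >= 2):
            v.append(Violation("scenario.n_subjects", f"must be an integer >= 2, got {n!r}"))
        noise = scen.get("noise_sd")
        if noise is not None and noise < 0:
            v.append(Violation("scenario.noise_sd", f"must be >= 0, got {noise}"))
    else:
        inputs = cfg.get("inputs") or {}
        for key in ("traces_csv", "timeline_file", "rpe_csv"):
            if not inputs.get(key):
                v.append(Violation(f"inputs.{key}", "required in real mode"))

    tl = cfg.get("timeline") or {}
    for key in ("baseline_s", "rest_s", "recovery_s"):
        val = tl.get(key)
        if val is not None and not val > 0:
            v.append(Violation(f"timeline.{key}", f"must be positive, got {val}"))
    sets = tl.get("set_durations_s") or []
    if not sets:
        v.append(Violation("timeline.set_durations_s", "at least one set is required"))
    for i, d in enumerate(sets):
        if not d > 0:
            v.append(Violation(f"timeline.set_durations_s[{i}]",
                               f"must be positive, got {d}"))

    bands = cfg.get("bands")
    if bands is not None and sorted(bands) != sorted(BAND_LABELS):
        v.append(Violation("bands",
                           f"band set must be exactly {sorted(BAND_LABELS)}, got {sorted(bands)}"))

    psd = cfg.get("psd") or {}
    if not (0 <= psd.get("overlap", 0.5) < 1):
        v.append(Violation("psd.overlap", "must be in [0, 1)"))
    if psd.get("segment_s", 150.0) <= 0:
        v.append(Violation("psd.segment_s", "must be positive"))

    st = cfg.get("stats") or {}
    if st.get("correction", "gg") not in ("gg", "hf", "none"):
        v.append(Violation("stats.correction", "must be 'gg', 'hf' or 'none'"))
    if st.get("rpe_agg", "last") not in ("last", "mean", "max"):
        v.append(Violation("stats.rpe_agg", "must be 'last', 'mean' or 'max'"))
    if not (0 < st.get("alpha", 0.05) < 1):
        v.append(Violation("stats.alpha", "must be in (0, 1)"))

    return v


def load_config(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    return merge_config(doc or {})


def aggregate_rpe(rpe_df: pd.DataFrame, how: str = "last") -> dict[str, int]:
    """One rating per subject from a tidy RPE table.

    Accepts either one row per subject (columns subject_id, rpe) or one row
    per subject x set (additional set_index column); multiple rows per
    subject are aggregated by the final-set value (default), mean, or max.
    """
    out: dict[str, int] = {}
    for sid, grp in rpe_df.groupby("subject_id", sort=False):
        vals = grp.sort_values("set_index")["rpe"] if "set_index" in grp else grp["rpe"]
        if how == "last":
            val = vals.iloc[-1]
        elif how == "mean":
            val = vals.mean()
        elif how == "max":
            val = vals.max()
        else:
            raise ValueError(f"unknown RPE aggregation {how!r}")
        out[str(sid)] = int(round(float(val)))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _write_cohort_traces(traces: dict[str, dict[str, ROITrace]], path: Path) -> None:
    parts = []
    for sid, by_roi in traces.items():
        for tr in by_roi.values():
            parts.append(pd.DataFrame({
                "subject_id": sid, "t_s": tr.times, "label": tr.label,
                "temp_C": tr.values,
            }))
    df = pd.concat(parts, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.9g")


def read_cohort_traces(path: str | Path, fs: float | None = None
                       ) -> dict[str, dict[str, ROITrace]]:
    """Read a multi-subject trace CSV (subject_id, t_s, label, temp_C)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        df = df.assign(subject_id="S01")
    out: dict[str, dict[str, ROITrace]] = {}
    for (sid, label), grp in df.groupby(["subject_id", "label"], sort=False):
        t = grp["t_s"].to_numpy()
        rate = fs if fs is not None else (
            1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0)
        out.setdefault(str(sid), {})[str(label)] = ROITrace(
            label=str(label), values=grp["temp_C"].to_numpy(),
            fs=round(rate, 9), t0_s=float(t[0]),
        )
    return out


def timeline_from_config(cfg: Mapping[str, Any]) -> SessionTimeline:
    tl = cfg["timeline"]
    return make_default_timeline(
        tl["set_durations_s"], tl["baseline_s"], tl["rest_s"], tl["recovery_s"]
    )


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest.

    Raises :class:`StageError` naming the failing stage; outputs of earlier
    stages are left on disk.
    """
    cfg = merge_config(config)
    violations = validate_config(cfg)
    if violations:
        msgs = "; ".join(f"{v.path}: {v.message}" for v in violations)
        raise StageError("config", f"invalid configuration: {msgs}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    outputs: dict[str, str] = {}

    psd_cfg = cfg["psd"]
    psd_settings = PsdSettings(
        segment_s=float(psd_cfg["segment_s"]), overlap=float(psd_cfg["overlap"]),
        window=psd_cfg["window"], detrend=psd_cfg["detrend"],
    )

    # --- stage: simulate / load inputs -----------------------------------
    if cfg["mode"] == "synthetic":
        try:
            timeline = timeline_from_config(cfg)
            scen = cfg["scenario"]
            spec = study_cohort_spec(
                n_subjects=scen.get("n_subjects", 8), seed=cfg["seed"]
            )
            cohort = synthesize_cohort(spec, timeline)
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc
        traces = cohort.traces
        rpe = cohort.rpe
        _write_cohort_traces(traces, out / "traces.csv")
        pd.DataFrame(
            [{"subject_id": s, "rpe": r} for s, r in rpe.items()]
        ).to_csv(out / "rpe.csv", index=False)
        cohort.truth.to_csv(out / "ground_truth.csv", index=False,
                            float_format="%.9g")
        (out / "timeline.json").write_text(
            json.dumps(timeline.to_dict(), sort_keys=True)
        )
        outputs["traces.csv"] = str(out / "traces.csv")
        outputs["rpe.csv"] = str(out / "rpe.csv")
        outputs["ground_truth.csv"] = str(out / "ground_truth.csv")
        outputs["timeline.json"] = str(out / "timeline.json")
    else:
        try:
            inputs = cfg["inputs"]
            traces = read_cohort_traces(inputs["traces_csv"])
            timeline = SessionTimeline.from_dict(
                yaml.safe_load(Path(inputs["timeline_file"]).read_text())
            )
            rpe = aggregate_rpe(
                pd.read_csv(inputs["rpe_csv"]), cfg["stats"]["rpe_agg"]
            )
        except Exception as exc:
            raise StageError("load", str(exc)) from exc

    # --- stage: features --------------------------------------------------
    try:
        # timeline-level feasibility first: a too-short baseline or recovery
        # invalidates every subject at once
        win = AnalysisWindows.from_timeline(timeline)
        bad = win.epoch_violations(timeline)
        for name in ("dt_baseline", "dt_final", "psd_pre", "psd_post"):
            start, end = getattr(win, name)
            if start < 0 or end > timeline.end_s:
                bad.append(name)
        if bad:
            raise ValueError(
                f"analysis window(s) {sorted(set(bad))} infeasible for this "
                "timeline (the 10-s pre-exercise and 5-min spectral windows "
                "must fit inside the baseline and recovery phases)"
            )
        table = compute_feature_table(
            traces, timeline, rpe, settings=psd_settings
        )
    except Exception as exc:
        raise StageError("features", str(exc)) from exc
    for sid, reason in table.exclusions:
        warnings.append(f"subject {sid} excluded: {reason}")
    if table.data.empty:
        raise StageError("features", "no subject survived window feasibility checks")
    table.data.to_csv(out / "features.csv", index=False, float_format="%.9g")
    outputs["features.csv"] = str(out / "features.csv")
    res_flags = {f for f in table.data["flags"] if f}
    for f in sorted(res_flags):
        warnings.append(f"feature flag: {f}")

    # --- stage: stats -----------------------------------------------------
    try:
        report = build_report(
            table.data,
            correction=cfg["stats"]["correction"],
            alpha=cfg["stats"]["alpha"],
        )
    except Exception as exc:
        raise StageError("stats", str(exc)) from exc
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    (report_dir / "report.json").write_text(report.to_json())
    (report_dir / "report.md").write_text(report.to_markdown())
    outputs["report/report.json"] = str(report_dir / "report.json")
    outputs["report/report.md"] = str(report_dir / "report.md")
    warnings.extend(report.warnings)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "checksums": {rel: _sha256(Path(p)) for rel, p in outputs.items()},
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest
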