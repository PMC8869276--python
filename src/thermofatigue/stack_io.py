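"""Reading and writing thermal frame stacks and trace tables.

A frame stack is stored either as a multi-page 32-bit float TIFF (one page
per frame, pixel values in degC) or as a directory of per-frame CSV matrices
with zero-padded frame indices in the filenames. Either form carries a JSON
sidecar with the sampling rate and units; units must be "degC" — the reader
refuses anything else rather than converting silently.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .trace import ROITrace

SIDECAR_NAME = "sidecar.json"
_FRAME_RE = re.compile(r"frame_(\d+)\.csv$")


@dataclass(frozen=True)
class ThermalFrameStack:
    """Ordered 2-D temperature images (degC) at a fixed frame rate."""

    frames: np.ndarray  # (n_frames, H, W), float32
    fs: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float32)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, H, W) array, n >= 1")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frames contain non-finite temperatures")
        object.__setattr__(self, "frames", frames)
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:]


def _sidecar_path(path: Path, fmt: str) -> Path:
    return path / SIDECAR_NAME if fmt == "csv_dir" else path.with_suffix(".json")


def write_frame_stack(
    stack: ThermalFrameStack,
    path: str | Path,
    fmt: str = "tiff",
    roi_ground_truth_paths: Mapping[str, np.ndarray] | None = None,
) -> Path:
    """Write a stack plus its JSON sidecar; returns the sidecar path.

    ``fmt="tiff"`` writes a multi-page float32 TIFF at ``path``;
    ``fmt="csv_dir"`` writes ``frame_0000.csv`` ... into directory ``path``.
    Ground-truth ROI paths from the simulator, if given, are stored in the
    sidecar for tracker validation.
    """
    path = Path(path)
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack.frames, photometric="minisblack")
    elif fmt == "csv_dir":
        path.mkdir(parents=True, exist_ok=True)
        ndigits = max(4, len(str(stack.n_frames - 1)))
        for i, frame in enumerate(stack.frames):
            np.savetxt(path / f"frame_{i:0{ndigits}d}.csv", frame, delimiter=",")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    sidecar = {
        "fs_hz": stack.fs,
        "units": "degC",
        "t0_s": stack.t0_s,
        "n_frames": stack.n_frames,
    }
    if roi_ground_truth_paths is not None:
        sidecar["roi_ground_truth_paths"] = {
            label: np.asarray(p).tolist()
            for label, p in roi_ground_truth_paths.items()
        }
    sc_path = _sidecar_path(path, fmt)
    sc_path.write_text(json.dumps(sidecar, sort_keys=True))
    return sc_path


def read_frame_stack(path: str | Path, fmt: str = "tiff") -> ThermalFrameStack:
    """Read a frame stack written by :func:`write_frame_stack`.

    Raises
    ------
    FileNotFoundError
        If the stack or its sidecar is missing.
    ValueError
        If the sidecar declares units other than degC, or frames are ragged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sc_path = _sidecar_path(path, fmt)
    if not sc_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    units = sidecar.get("units")
    if units != "degC":
        raise ValueError(
            f"sidecar declares units {units!r}; this reader accepts degC only "
            "(no silent conversion)"
        )

    if fmt == "tiff":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    elif fmt == "csv_dir":
        entries = sorted(
            (m.group(1), p)
            for p in path.iterdir()
            if (m := _FRAME_RE.search(p.name))
        )
        if not entries:
            raise FileNotFoundError(f"no frame_*.csv files in {path}")
        mats = [np.loadtxt(p, delimiter=",", ndmin=2) for _, p in entries]
        shapes = {m.shape for m in mats}
        if len(shapes) > 1:
            offenders = [
                str(p) for (_, p), m in zip(entries, mats) if m.shape != mats[0].shape
            ]
            raise ValueError(f"ragged frame shapes; offending files: {offenders}")
        frames = np.stack(mats)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    return ThermalFrameStack(
        frames=frames, fs=float(sidecar["fs_hz"]), t0_s=float(sidecar.get("t0_s", 0.0))
    )


def read_ground_truth_paths(path: str | Path, fmt: str = "tiff") -> dict[str, np.ndarray]:
    """ROI ground-truth top-left paths stored in the sidecar, if any."""
    sidecar = json.loads(_sidecar_path(Path(path), fmt).read_text())
    return {
        label: np.asarray(p, dtype=np.int64)
        for label, p in sidecar.get("roi_ground_truth_paths", {}).items()
    }


def write_traces(traces: Mapping[str, ROITrace] | list[ROITrace], path: str | Path) -> None:
    """Write traces as tidy CSV with columns (t_s, label, temp_C)."""
    if isinstance(traces, Mapping):
        traces = list(traces.values())
    parts = [
        pd.DataFrame({"t_s": tr.times, "label": tr.label, "temp_C": tr.values})
        for tr in traces
    ]
    df = pd.concat(parts, ignore_index=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")


def read_traces(path: str | Path) -> dict[str, ROITrace]:
    """Read a tidy trace CSV back into per-label traces."""
    df = pd.read_csv(path)
    out: dict[str, ROITrace] = {}
    for label, grp in df.groupby("label", sort=False):
        t = grp["t_s"].to_numpy()
        if len(t) > 1:
            dt = np.diff(t)
            fs = 1.0 / np.median(dt)
        else:
            fs = 1.0
        out[str(label)] = ROITrace(
            label=str(label), values=grp["temp_C"].to_numpy(), fs=round(fs, 9),
            t0_s=float(t[0]),
        )
    return out
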