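"""Render ROI temperature traces into synthetic thermal frame stacks.

Each ROI is a rectangular patch over an ambient-temperature background.
The patch's pixel weights are normalised so that the arithmetic mean of the
in-patch pixels equals the driving trace value exactly (before pixel noise),
whether the profile is uniform or Gaussian-edged. Patches may translate over
time (linear drift or sinusoidal sway, in whole pixels); the ground-truth
top-left path of every patch is returned alongside the stack so trackers can
be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..stack_io import ThermalFrameStack
from ..trace import ROITrace


@dataclass(frozen=True)
class ROIPatch:
    """Placement and spatial profile of one ROI at frame 0.

    x0, y0 are the top-left pixel (0-based; x indexes columns, y rows);
    the patch spans ``width`` columns and ``height`` rows inclusive of the
    top-left pixel. ``profile`` is "uniform" or "gaussian" (a Gaussian-edged
    bump centred in the box with SD ``gaussian_sigma_frac`` times the box
    half-extent).
    """

    label: str
    x0: int
    y0: int
    width: int
    height: int
    profile: str = "uniform"
    gaussian_sigma_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"patch {self.label!r}: width/height must be >= 1")
        if self.profile not in ("uniform", "gaussian"):
            raise ValueError(f"patch {self.label!r}: unknown profile {self.profile!r}")

    def weights(self) -> np.ndarray:
        """Pixel weights, normalised to mean 1 over the box."""
        if self.profile == "uniform":
            return np.ones((self.height, self.width))
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        cy, cx = (self.height - 1) / 2.0, (self.width - 1) / 2.0
        sy = max(self.gaussian_sigma_frac * self.height / 2.0, 1e-6)
        sx = max(self.gaussian_sigma_frac * self.width / 2.0, 1e-6)
        w = np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
        return w / w.mean()


def _motion_offsets(motion: Mapping | None, n_frames: int, fs: float) -> np.ndarray:
    """Integer (dx, dy) offsets per frame for one patch."""
    out = np.zeros((n_frames, 2), dtype=np.int64)
    if motion is None or motion.get("type", "static") == "static":
        return out
    kind = motion["type"]
    frac = np.arange(n_frames) / max(n_frames - 1, 1)
    if kind == "linear":
        out[:, 0] = np.round(motion.get("dx", 0.0) * frac)
        out[:, 1] = np.round(motion.get("dy", 0.0) * frac)
    elif kind == "sinusoid":
        t = np.arange(n_frames) / fs
        w = 2.0 * np.pi / motion["period_s"]
        out[:, 0] = np.round(motion.get("amp_x", 0.0) * np.sin(w * t))
        out[:, 1] = np.round(motion.get("amp_y", 0.0) * np.sin(w * t))
    else:
        raise ValueError(f"unknown motion type {kind!r}")
    return out


@dataclass(frozen=True)
class SceneLayout:
    """Image geometry: patch placements and per-ROI motion paths.

    ``motion`` maps ROI label to a motion spec dict:
    ``{"type": "static"}``, ``{"type": "linear", "dx": ..., "dy": ...}``
    (total drift in pixels over the whole video) or
    ``{"type": "sinusoid", "amp_x": ..., "amp_y": ..., "period_s": ...}``.
    """

    shape: tuple[int, int]  # (H, W)
    patches: tuple[ROIPatch, ...]
    motion: Mapping[str, Mapping] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "patches", tuple(self.patches))
        h, w = self.shape
        labels = [p.label for p in self.patches]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate patch labels")
        for p in self.patches:
            if p.x0 < 0 or p.y0 < 0 or p.x0 + p.width > w or p.y0 + p.height > h:
                raise ValueError(
                    f"patch {p.label!r} outside image bounds {self.shape} at frame 0"
                )
        # non-overlap at frame-0 positions
        occupancy = np.zeros(self.shape, dtype=bool)
        for p in self.patches:
            region = occupancy[p.y0 : p.y0 + p.height, p.x0 : p.x0 + p.width]
            if region.any():
                raise ValueError(f"patch {p.label!r} overlaps another patch")
            region[:] = True


def synthesize_frames(
    traces: Mapping[str, ROITrace],
    layout: SceneLayout,
    ambient_temp: float = 24.0,
    pixel_noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> tuple[ThermalFrameStack, dict[str, np.ndarray]]:
    """Render traces into a frame stack.

    Returns the stack and, per ROI label, the ground-truth top-left path as
    an (n_frames, 2) integer array of (x0, y0).

    Raises
    ------
    ValueError
        If traces differ in length or rate, if a label has no patch, or if
        motion carries a patch outside the image (the error names the first
        offending frame).
    """
    lengths = {len(tr) for tr in traces.values()}
    rates = {tr.fs for tr in traces.values()}
    if len(lengths) != 1 or len(rates) != 1:
        raise ValueError("all traces must share length and sampling rate")
    (n_frames,) = lengths
    (fs,) = rates
    patch_by_label = {p.label: p for p in layout.patches}
    missing = set(traces) - set(patch_by_label)
    if missing:
        raise ValueError(f"no patch for trace labels: {sorted(missing)}")

    h, w = layout.shape
    paths: dict[str, np.ndarray] = {}
    for label in traces:
        p = patch_by_label[label]
        offs = _motion_offsets(layout.motion.get(label), n_frames, fs)
        path = offs + np.array([p.x0, p.y0])
        bad = np.nonzero(
            (path[:, 0] < 0)
            | (path[:, 1] < 0)
            | (path[:, 0] + p.width > w)
            | (path[:, 1] + p.height > h)
        )[0]
        if bad.size:
            raise ValueError(
                f"patch {label!r} leaves image bounds at frame {int(bad[0])}"
            )
        paths[label] = path

    weights = {label: patch_by_label[label].weights() for label in traces}
    frames = np.full((n_frames, h, w), ambient_temp, dtype=np.float64)
    for label, tr in traces.items():
        p = patch_by_label[label]
        wgt = weights[label]
        path = paths[label]
        for i in range(n_frames):
            x, y = path[i]
            frames[i, y : y + p.height, x : x + p.width] = (
                ambient_temp + (tr.values[i] - ambient_temp) * wgt
            )

    if pixel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames += rng.normal(0.0, pixel_noise_sd, size=frames.shape)

    stack = ThermalFrameStack(frames=frames.astype(np.float32), fs=fs)
    return stack, paths
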