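"""ROI tracking across thermal frames and trace extraction.

Tracking is frame-to-frame normalised cross-correlation (NCC) template
matching: the template is the ROI's pixel content, the search window extends
a fixed radius around the previous position, and the template is refreshed
periodically from the tracked position so slow appearance changes (the skin
warming or cooling) do not starve the correlation. The subject sits on an
exercise machine, so ROI motion is rigid and slow; whole-pixel NCC is
sufficient and fully deterministic.

Frames whose best correlation falls below a threshold — including degenerate
featureless frames where NCC is undefined — keep the previous position and
are flagged, never interpolated, so tracking failures stay visible
downstream.

Coordinates are 0-based throughout: x indexes columns, y rows; a box covers
``width`` columns and ``height`` rows starting at its top-left pixel (x0, y0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .stack_io import ThermalFrameStack
from .trace import ROITrace


@dataclass(frozen=True)
class ROIBox:
    label: str
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"box {self.label!r}: width/height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"box {self.label!r}: x0/y0 must be >= 0")

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x0 + self.width > w or self.y0 + self.height > h:
            raise ValueError(
                f"box {self.label!r} ({self.x0},{self.y0},{self.width},"
                f"{self.height}) outside image of shape {shape}"
            )


@dataclass(frozen=True)
class TrackSettings:
    """NCC tracker knobs.

    search_radius : pixels searched around the previous position (each axis).
    refresh_every : template is re-cut from the tracked position every this
        many frames; 0 disables refresh.
    min_score : NCC below this holds the previous position and flags the
        frame. NCC is in [-1, 1].
    """

    search_radius: int = 10
    refresh_every: int = 50
    min_score: float = 0.5


@dataclass(frozen=True)
class ROITrackResult:
    """Per-frame box positions (top-left), NCC scores and confidence flags."""

    label: str
    width: int
    height: int
    positions: np.ndarray  # (n_frames, 2) int, columns (x0, y0)
    scores: np.ndarray  # (n_frames,) float in [-1, 1]
    flagged: np.ndarray  # (n_frames,) bool — low-confidence frames

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def displacement(self) -> np.ndarray:
        """Per-frame displacement from the initial position, pixels."""
        return self.positions - self.positions[0]


def _cut(frame: np.ndarray, x: int, y: int, w: int, h: int) -> np.ndarray:
    return frame[y : y + h, x : x + w]


def track_roi(
    stack: ThermalFrameStack,
    initial: ROIBox,
    settings: TrackSettings | None = None,
) -> ROITrackResult:
    """Track one ROI through the stack by NCC template matching."""
    settings = settings or TrackSettings()
    initial.validate_within(stack.shape)
    img_h, img_w = stack.shape
    w, h = initial.width, initial.height
    r = settings.search_radius

    n = stack.n_frames
    positions = np.zeros((n, 2), dtype=np.int64)
    scores = np.ones(n, dtype=np.float64)
    flagged = np.zeros(n, dtype=bool)

    x, y = initial.x0, initial.y0
    positions[0] = (x, y)
    template = np.asarray(_cut(stack.frames[0], x, y, w, h), dtype=np.float64)

    for i in range(1, n):
        frame = np.asarray(stack.frames[i], dtype=np.float64)
        sx0, sy0 = max(0, x - r), max(0, y - r)
        sx1, sy1 = min(img_w, x + w + r), min(img_h, y + h + r)
        search = frame[sy0:sy1, sx0:sx1]

        if np.ptp(template) == 0.0 or np.ptp(search) == 0.0:
            score = 0.0  # NCC undefined on constant images
        else:
            corr = match_template(search, template)
            corr = np.nan_to_num(corr, nan=0.0)
            iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
            score = float(corr[iy, ix])

        if score < settings.min_score:
            flagged[i] = True  # hold previous position
        else:
            x, y = sx0 + int(ix), sy0 + int(iy)
        positions[i] = (x, y)
        scores[i] = score

        if settings.refresh_every and i % settings.refresh_every == 0 and not flagged[i]:
            template = np.asarray(_cut(frame, x, y, w, h), dtype=np.float64)

    return ROITrackResult(
        label=initial.label, width=w, height=h,
        positions=positions, scores=scores, flagged=flagged,
    )


def static_track(stack: ThermalFrameStack, box: ROIBox) -> ROITrackResult:
    """Track result that keeps the box fixed on every frame (no tracking)."""
    box.validate_within(stack.shape)
    n = stack.n_frames
    positions = np.tile([box.x0, box.y0], (n, 1)).astype(np.int64)
    return ROITrackResult(
        label=box.label, width=box.width, height=box.height,
        positions=positions, scores=np.ones(n), flagged=np.zeros(n, dtype=bool),
    )


def extract_trace(stack: ThermalFrameStack, track: ROITrackResult) -> ROITrace:
    """Mean temperature of the tracked box on every frame."""
    if track.n_frames != stack.n_frames:
        raise ValueError(
            f"track has {track.n_frames} positions for {stack.n_frames} frames"
        )
    values = np.empty(stack.n_frames, dtype=np.float64)
    for i in range(stack.n_frames):
        x, y = track.positions[i]
        values[i] = float(
            np.mean(
                stack.frames[i, y : y + track.height, x : x + track.width],
                dtype=np.float64,
            )
        )
    return ROITrace(label=track.label, values=values, fs=stack.fs, t0_s=stack.t0_s)
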