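"""Per-frame activity-status classification.

Each frame is reduced to one of four statuses by comparing the
Euclidean distance of the tracked box center to a reference position
P0 between consecutive frames:

* ``+1`` — the distance grew by at least ε (moving away from the bed),
* ``-1`` — the distance shrank by at least ε (moving toward the bed),
* ``0``  — the change is below ε (neutral),
* ``-2`` — no bounding box in the frame.

ε is the distance threshold in pixels. P0 can be the image origin, a
fixed bed-anchored point, or the first detected position. When several
boxes are present, the tracked position is the center of the
highest-priority label (head before trunk by default), breaking ties by
confidence. Across detection dropouts the last observed position is
carried, so a reappearing object is compared against where it was last
seen rather than resetting.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .trace_io import BoundingBox, DetectionTrace, FrameDetection

Position = tuple[float, float]

#: Status code meaning "no bounding box in this frame".
NO_BOX = -2

DEFAULT_LABEL_PRIORITY = ("head", "trunk")


@dataclass(frozen=True)
class StatusSample:
    """One frame's classified status, with the position that produced it.

    ``position`` is the selected track center, or None exactly when
    ``status == -2``.
    """

    frame_index: int
    time_s: float
    status: int
    position: Optional[Position] = None

    def __post_init__(self) -> None:
        if self.status not in (1, 0, -1, -2):
            raise ValueError(f"invalid status {self.status}")
        if (self.status == NO_BOX) != (self.position is None):
            raise ValueError("position must be absent iff status is -2")


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of the status-classification stage.

    Parameters
    ----------
    epsilon : float
        Distance threshold ε in pixels (≥ 0). Default 5 px at 640×360
        input scale: small relative to the image diagonal, large
        relative to sub-pixel detector jitter.
    p0_mode : {"origin", "fixed", "first_detection"}
        How the reference position P0 is resolved. "origin" uses the
        top-left pixel (0, 0); "fixed" uses ``p0_fixed``;
        "first_detection" uses the first frame with a selected position.
    p0_fixed : (float, float), optional
        Required iff ``p0_mode == "fixed"``.
    label_priority : tuple of str
        Box labels in decreasing tracking priority.
    """

    epsilon: float = 5.0
    p0_mode: str = "origin"
    p0_fixed: Optional[Position] = None
    label_priority: tuple[str, ...] = DEFAULT_LABEL_PRIORITY

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.p0_mode not in ("origin", "fixed", "first_detection"):
            raise ValueError(f"unknown p0_mode {self.p0_mode!r}")
        if (self.p0_mode == "fixed") != (self.p0_fixed is not None):
            raise ValueError("p0_fixed is required iff p0_mode='fixed'")


def center_of(box: BoundingBox) -> Position:
    """Return the box center (cx, cy); boxes store centers natively."""
    return (box.cx, box.cy)


def select_position(
    frame: FrameDetection, priority: Sequence[str] = DEFAULT_LABEL_PRIORITY
) -> Optional[Position]:
    """Pick the tracked position for a frame, or None if no boxes.

    The first priority label present wins; within a label the
    highest-confidence box wins. Labels outside the priority list are
    considered last, in their stored order.
    """
    if not frame.boxes:
        return None
    rank = {label: i for i, label in enumerate(priority)}
    best = min(
        frame.boxes,
        key=lambda b: (rank.get(b.label, len(priority)), -b.conf),
    )
    return center_of(best)


def window_frame_count(W: float, R: float) -> int:
    """Number of frames in a time slot of W seconds at R fps (uF = W×R).

    Rounded to the nearest integer, never below 1.
    """
    if W <= 0 or R <= 0:
        raise ValueError(f"W and R must be positive, got W={W}, R={R}")
    return max(1, round(W * R))


def _dist(p: Position, q: Position) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def classify_status(
    prev_pos: Optional[Position],
    cur_pos: Optional[Position],
    p0: Position,
    epsilon: float,
) -> int:
    """Classify one frame transition into a status code.

    With d(·) the Euclidean distance to ``p0``: an absent current
    position is −2; d(cur) − d(prev) ≥ ε is +1; d(prev) − d(cur) ≥ ε is
    −1; otherwise 0. ``prev_pos=None`` means no position has ever been
    observed, in which case P0 itself stands in for the previous
    position.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if cur_pos is None:
        return NO_BOX
    if prev_pos is None:
        prev_pos = p0
    delta = _dist(cur_pos, p0) - _dist(prev_pos, p0)
    if delta >= epsilon:
        return 1
    if -delta >= epsilon:
        return -1
    return 0


def resolve_p0(trace: DetectionTrace, cfg: ClassifierConfig) -> Position:
    """Resolve the reference position P0 for a trace under ``cfg``."""
    if cfg.p0_mode == "origin":
        return (0.0, 0.0)
    if cfg.p0_mode == "fixed":
        assert cfg.p0_fixed is not None
        return cfg.p0_fixed
    for frame in trace:
        pos = select_position(frame, cfg.label_priority)
        if pos is not None:
            return pos
    raise ValueError(
        "p0_mode='first_detection' requires at least one frame with a detection"
    )


def classify_trace(
    trace: DetectionTrace, cfg: ClassifierConfig | None = None
) -> tuple[StatusSample, ...]:
    """Classify every frame of a trace into a status stream.

    P0 is resolved once per trace. The previous position carries across
    −2 gaps: after a dropout the reappearing object is compared against
    its last observed position. The first detected frame is compared
    against P0.
    """
    cfg = cfg or ClassifierConfig()
    p0 = resolve_p0(trace, cfg)
    samples: list[StatusSample] = []
    last_pos: Optional[Position] = None
    for frame in trace:
        pos = select_position(frame, cfg.label_priority)
        status = classify_status(last_pos, pos, p0, cfg.epsilon)
        samples.append(
            StatusSample(
                frame_index=frame.frame_index,
                time_s=frame.time_s,
                status=status,
                position=pos,
            )
        )
        if pos is not None:
            last_pos = pos
    return tuple(samples)


def write_status_stream(samples: Iterable[StatusSample], path: str | Path) -> None:
    """Write a status stream as CSV (frame, t, status, cx, cy)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "t", "status", "cx", "cy"])
        for s in samples:
            cx, cy = ("", "") if s.position is None else (repr(s.position[0]), repr(s.position[1]))
            writer.writerow([s.frame_index, repr(s.time_s), s.status, cx, cy])
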