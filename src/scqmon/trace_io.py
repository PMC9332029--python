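"""Domain types and file formats for detection traces and ground truth.

A *detection trace* is the output of the (out-of-process) object
detection stage: for every video frame, zero or more labeled bounding
boxes. Two plain-text encodings are supported:

* JSONL — one object per frame:
  ``{"frame": int, "t": float, "boxes": [{"label", "cx", "cy", "w", "h", "conf"}]}``
* CSV — one row per box (``frame,t,label,cx,cy,w,h,conf``); a frame with
  no detections is a row with empty box columns, so the "no bounding
  box" state is preserved explicitly.

Ground-truth behavior segments are a CSV of
``behavior,start_frame,end_frame`` with inclusive, non-overlapping,
ordered frame ranges.

Floats are serialized with :func:`repr`, which round-trips exactly, so
write-then-read is the identity on every valid trace.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class Behavior(str, Enum):
    """The four bed-related behaviors recognized by the pipeline."""

    ON_BED = "on_bed"
    OFF_BED = "off_bed"
    RETURN = "return"
    NOBODY = "nobody"


class TraceParseError(ValueError):
    """A file row could not be parsed; the message names the line."""


class TraceValidationError(ValueError):
    """Parsed data violates a trace or segment invariant."""


@dataclass(frozen=True)
class BoundingBox:
    """One detection: a labeled box in image-pixel coordinates.

    Coordinates are box centers; the image origin (0, 0) is the
    top-left pixel, x increasing rightward and y downward.
    """

    label: str
    cx: float
    cy: float
    w: float
    h: float
    conf: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise TraceValidationError(
                f"box width/height must be positive, got {self.w}x{self.h}"
            )
        if not (0.0 <= self.conf <= 1.0):
            raise TraceValidationError(f"confidence must be in [0,1], got {self.conf}")

    @classmethod
    def from_corner(
        cls, label: str, x0: float, y0: float, w: float, h: float, conf: float = 1.0
    ) -> "BoundingBox":
        """Build from top-left-corner form, converting to center form."""
        return cls(label=label, cx=x0 + w / 2.0, cy=y0 + h / 2.0, w=w, h=h, conf=conf)


@dataclass(frozen=True)
class FrameDetection:
    """All detections of a single frame; ``boxes`` may be empty."""

    frame_index: int
    time_s: float
    boxes: tuple[BoundingBox, ...] = ()

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise TraceValidationError(f"negative frame index {self.frame_index}")
        object.__setattr__(self, "boxes", tuple(self.boxes))


@dataclass(frozen=True)
class BehaviorSegment:
    """A contiguous ground-truth span of one behavior (frames inclusive)."""

    behavior: Behavior
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "behavior", Behavior(self.behavior))
        if self.start_frame > self.end_frame:
            raise TraceValidationError(
                f"segment start {self.start_frame} > end {self.end_frame}"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def contains(self, frame: int) -> bool:
        return self.start_frame <= frame <= self.end_frame


@dataclass(frozen=True)
class DetectionTrace:
    """An ordered sequence of per-frame detections at a fixed frame rate."""

    frames: tuple[FrameDetection, ...]
    frame_rate: float = 15.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise TraceValidationError(f"frame rate must be > 0, got {self.frame_rate}")
        object.__setattr__(self, "frames", tuple(self.frames))
        prev_idx, prev_t = -1, float("-inf")
        for f in self.frames:
            if f.frame_index <= prev_idx:
                raise TraceValidationError(
                    f"frame indices must strictly increase: {f.frame_index} "
                    f"after {prev_idx}"
                )
            if f.time_s < prev_t:
                raise TraceValidationError(
                    f"timestamps must be nondecreasing: {f.time_s} after {prev_t}"
                )
            prev_idx, prev_t = f.frame_index, f.time_s

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


_CSV_HEADER = ["frame", "t", "label", "cx", "cy", "w", "h", "conf"]
_BOX_FIELDS = ["label", "cx", "cy", "w", "h", "conf"]


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        if format not in ("jsonl", "csv"):
            raise ValueError(f"unknown trace format {format!r}")
        return format
    suffix = Path(path).suffix.lower()
    return "jsonl" if suffix in (".jsonl", ".json") else "csv"


def read_trace(
    path: str | Path, format: str | None = None, frame_rate: float = 15.0
) -> DetectionTrace:
    """Read a detection trace from a JSONL or CSV file.

    ``format`` defaults from the file suffix (``.jsonl``/``.json`` →
    JSONL, else CSV). Frames with no box fields yield empty
    ``FrameDetection.boxes``. Raises :class:`TraceParseError` naming the
    offending line on malformed input, :class:`TraceValidationError` on
    non-monotone frame indices.
    """
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        frames = _read_jsonl(path)
    else:
        frames = _read_csv(path)
    return DetectionTrace(frames=tuple(frames), frame_rate=frame_rate)


def _read_jsonl(path: str | Path) -> list[FrameDetection]:
    frames: list[FrameDetection] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                boxes = tuple(
                    BoundingBox(
                        label=b["label"], cx=float(b["cx"]), cy=float(b["cy"]),
                        w=float(b["w"]), h=float(b["h"]), conf=float(b["conf"]),
                    )
                    for b in obj.get("boxes", [])
                )
                frames.append(
                    FrameDetection(
                        frame_index=int(obj["frame"]),
                        time_s=float(obj["t"]),
                        boxes=boxes,
                    )
                )
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                if isinstance(exc, TraceValidationError):
                    raise
                raise TraceParseError(f"{path}: malformed JSONL at line {lineno}: {exc}")
    return frames


def _read_csv(path: str | Path) -> list[FrameDetection]:
    # One row per box; rows sharing a frame index are merged into one frame.
    by_frame: dict[int, dict] = {}
    order: list[int] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[:2] != ["frame", "t"]:
            raise TraceParseError(f"{path}: expected CSV header {_CSV_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            try:
                idx = int(row["frame"])
                t = float(row["t"])
                if idx not in by_frame:
                    by_frame[idx] = {"t": t, "boxes": []}
                    order.append(idx)
                if row.get("label"):
                    by_frame[idx]["boxes"].append(
                        BoundingBox(
                            label=row["label"], cx=float(row["cx"]),
                            cy=float(row["cy"]), w=float(row["w"]),
                            h=float(row["h"]), conf=float(row["conf"]),
                        )
                    )
            except (KeyError, TypeError, ValueError) as exc:
                if isinstance(exc, TraceValidationError):
                    raise
                raise TraceParseError(f"{path}: malformed CSV at line {lineno}: {exc}")
    return [
        FrameDetection(frame_index=i, time_s=by_frame[i]["t"],
                       boxes=tuple(by_frame[i]["boxes"]))
        for i in order
    ]


def write_trace(trace: DetectionTrace, path: str | Path, format: str | None = None) -> None:
    """Write a trace so that :func:`read_trace` recovers it exactly."""
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for f in trace.frames:
                obj = {
                    "frame": f.frame_index,
                    "t": f.time_s,
                    "boxes": [
                        {"label": b.label, "cx": b.cx, "cy": b.cy,
                         "w": b.w, "h": b.h, "conf": b.conf}
                        for b in f.boxes
                    ],
                }
                fh.write(json.dumps(obj) + "\n")
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for f in trace.frames:
                if not f.boxes:
                    writer.writerow([f.frame_index, repr(f.time_s)] + [""] * 6)
                else:
                    for b in f.boxes:
                        writer.writerow(
                            [f.frame_index, repr(f.time_s), b.label,
                             repr(b.cx), repr(b.cy), repr(b.w), repr(b.h),
                             repr(b.conf)]
                        )


def read_segments(path: str | Path) -> tuple[BehaviorSegment, ...]:
    """Read ground-truth behavior segments (CSV ``behavior,start_frame,end_frame``).

    Rows may appear in any order; the result is sorted by start frame.
    Overlapping segments raise :class:`TraceValidationError`.
    """
    segments: list[BehaviorSegment] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                segments.append(
                    BehaviorSegment(
                        behavior=Behavior(row["behavior"]),
                        start_frame=int(row["start_frame"]),
                        end_frame=int(row["end_frame"]),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                if isinstance(exc, TraceValidationError):
                    raise
                raise TraceParseError(f"{path}: malformed segment at line {lineno}: {exc}")
    segments.sort(key=lambda s: s.start_frame)
    for a, b in zip(segments, segments[1:]):
        if b.start_frame <= a.end_frame:
            raise TraceValidationError(
                f"segments overlap: [{a.start_frame},{a.end_frame}] and "
                f"[{b.start_frame},{b.end_frame}]"
            )
    return tuple(segments)


def write_segments(segments: Iterable[BehaviorSegment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["behavior", "start_frame", "end_frame"])
        for s in segments:
            writer.writerow([s.behavior.value, s.start_frame, s.end_frame])
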