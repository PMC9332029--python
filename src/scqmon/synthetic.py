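"""Seeded simulator of narrow-field-of-view detection traces.

Real bed-side cameras with a narrow field of view produce clean scenes
but lossy detections: the head or trunk drops out for a few frames,
boxes flicker on and off during fast scene changes, and an on-bed
patient turning over produces abrupt position jitter. This module
scripts a sequence of behaviors (on bed, off bed, nobody, return) and
renders it into a :class:`~scqmon.trace_io.DetectionTrace` plus
ground-truth :class:`~scqmon.trace_io.BehaviorSegment` tiling, with
those failure modes injected on demand.

Trajectory model: on-bed positions are the bed anchor plus Gaussian
jitter; exits are a linear transit from the bed anchor to the exit
anchor at constant speed (return is the reverse); nobody segments have
no boxes. The tracked label switches head→trunk at the midpoint of an
exit (and trunk→head on a return), mirroring what a detector sees as
the patient stands up and walks. Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .trace_io import (
    Behavior,
    BehaviorSegment,
    BoundingBox,
    DetectionTrace,
    FrameDetection,
)

# Box extents at 640x360 scale; statuses depend only on centers, so
# sizes are cosmetic.
_HEAD_WH = (40.0, 40.0)
_TRUNK_WH = (80.0, 120.0)


@dataclass(frozen=True)
class Scenario:
    """A scripted behavior sequence plus noise/failure parameters.

    Parameters
    ----------
    segments : sequence of (Behavior, duration_s)
        The behavior script; durations in seconds, all > 0.
    R : float
        Frame rate in fps.
    image_size : (int, int)
        Image width and height in pixels; anchors must lie inside.
    bed_anchor, exit_anchor : (float, float)
        Pixel positions of the on-bed resting point and the off-bed
        end point of an exit transit.
    jitter_sigma : float
        Per-frame Gaussian position noise, pixels.
    speed : float
        Transit speed for exits/returns, pixels per second.
    dropouts : sequence of (start_frame, length_frames)
        Windows where detections are blanked (missed boxes).
    flickers : sequence of (start_frame, length_frames)
        Windows where detections alternate present/absent per frame.
    turn_over_bursts : bool
        Model occasional on-bed activity (turning over, sitting up) as
        jitter bursts at 3x sigma, clipped to ``burst_clip`` so they
        stay below the status threshold. Default on.
    burst_clip : float
        Maximum burst excursion from the bed anchor, pixels.
    seed : int
        Seed for all randomness.
    """

    segments: tuple[tuple[Behavior, float], ...]
    R: float = 15.0
    image_size: tuple[int, int] = (640, 360)
    bed_anchor: tuple[float, float] = (160.0, 90.0)
    exit_anchor: tuple[float, float] = (480.0, 270.0)
    jitter_sigma: float = 1.0
    speed: float = 180.0
    dropouts: tuple[tuple[int, int], ...] = ()
    flickers: tuple[tuple[int, int], ...] = ()
    turn_over_bursts: bool = True
    burst_clip: float = 2.25
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "segments",
            tuple((Behavior(b), float(d)) for b, d in self.segments),
        )
        object.__setattr__(self, "dropouts", tuple((int(a), int(b)) for a, b in self.dropouts))
        object.__setattr__(self, "flickers", tuple((int(a), int(b)) for a, b in self.flickers))
        if not self.segments:
            raise ValueError("scenario needs at least one segment")
        if any(d <= 0 for _, d in self.segments):
            raise ValueError("segment durations must be > 0")
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        w, h = self.image_size
        for name, (x, y) in (("bed_anchor", self.bed_anchor), ("exit_anchor", self.exit_anchor)):
            if not (0 <= x <= w and 0 <= y <= h):
                raise ValueError(f"{name} {x, y} outside image {w}x{h}")
        n = self.n_frames
        for kind, windows in (("dropout", self.dropouts), ("flicker", self.flickers)):
            for start, length in windows:
                if length < 1 or start < 0 or start + length > n:
                    raise ValueError(
                        f"{kind} window ({start},{length}) outside trace of {n} frames"
                    )

    @property
    def segment_frame_counts(self) -> tuple[int, ...]:
        return tuple(max(1, round(d * self.R)) for _, d in self.segments)

    @property
    def n_frames(self) -> int:
        return sum(self.segment_frame_counts)


@dataclass(frozen=True)
class GeneratedCase:
    """A simulated trace, its ground truth, and the scenario that made it."""

    trace: DetectionTrace
    truth: tuple[BehaviorSegment, ...]
    scenario: Scenario


def _unit(p: tuple[float, float], q: tuple[float, float]) -> tuple[tuple[float, float], float]:
    dx, dy = q[0] - p[0], q[1] - p[1]
    length = math.hypot(dx, dy)
    return (dx / length, dy / length), length


def generate(scenario: Scenario) -> GeneratedCase:
    """Render a scenario into a detection trace with tiled ground truth."""
    rng = np.random.default_rng(scenario.seed)
    counts = scenario.segment_frame_counts
    n_frames = scenario.n_frames
    R = scenario.R

    # (position or None, label) per frame, before failure injection
    track: list[tuple[Optional[tuple[float, float]], str]] = []
    for (behavior, _), n_seg in zip(scenario.segments, counts):
        if behavior is Behavior.NOBODY:
            track.extend([(None, "")] * n_seg)
            continue
        if behavior is Behavior.ON_BED:
            for i in range(n_seg):
                if scenario.turn_over_bursts and rng.random() < 0.08:
                    off = rng.normal(0.0, 3.0 * scenario.jitter_sigma, 2)
                    norm = math.hypot(*off)
                    if norm > scenario.burst_clip:
                        off = off * (scenario.burst_clip / norm)
                else:
                    off = rng.normal(0.0, scenario.jitter_sigma, 2)
                track.append(
                    ((scenario.bed_anchor[0] + off[0], scenario.bed_anchor[1] + off[1]),
                     "head")
                )
            continue
        # transit: off_bed goes bed -> exit, return goes exit -> bed
        if behavior is Behavior.OFF_BED:
            src, dst = scenario.bed_anchor, scenario.exit_anchor
            labels = ("head", "trunk")
        else:  # RETURN
            src, dst = scenario.exit_anchor, scenario.bed_anchor
            labels = ("trunk", "head")
        direction, path_len = _unit(src, dst)
        for i in range(n_seg):
            dist = min(scenario.speed * (i + 1) / R, path_len)
            jx, jy = rng.normal(0.0, scenario.jitter_sigma, 2)
            pos = (src[0] + direction[0] * dist + jx, src[1] + direction[1] * dist + jy)
            label = labels[0] if i < n_seg // 2 else labels[1]
            track.append((pos, label))

    # failure injection: dropouts blank whole windows, flickers blank
    # every other frame of the window (sudden appear/disappear)
    blanked = [False] * n_frames
    for start, length in scenario.dropouts:
        for f in range(start, start + length):
            blanked[f] = True
    for start, length in scenario.flickers:
        for f in range(start, start + length):
            if (f - start) % 2 == 1:
                blanked[f] = True

    frames = []
    for f in range(n_frames):
        pos, label = track[f]
        boxes: tuple[BoundingBox, ...] = ()
        if pos is not None and not blanked[f]:
            w, h = _HEAD_WH if label == "head" else _TRUNK_WH
            boxes = (
                BoundingBox(
                    label=label, cx=pos[0], cy=pos[1], w=w, h=h,
                    conf=float(rng.uniform(0.6, 0.99)),
                ),
            )
        frames.append(FrameDetection(frame_index=f, time_s=f / R, boxes=boxes))

    truth = []
    start = 0
    for (behavior, _), n_seg in zip(scenario.segments, counts):
        truth.append(
            BehaviorSegment(behavior=behavior, start_frame=start, end_frame=start + n_seg - 1)
        )
        start += n_seg

    return GeneratedCase(
        trace=DetectionTrace(frames=tuple(frames), frame_rate=R),
        truth=tuple(truth),
        scenario=scenario,
    )


def two_cycle_scenario(
    angle_profile: str = "horizontal", seed: int = 0, clean: bool = False
) -> Scenario:
    """A full monitoring sequence: the patient lies on the bed, exits,
    is gone, returns — twice — ending on the bed (9 behaviors).

    The ``horizontal`` profile has a long exit path and a few multi-frame
    detection dropouts during on-bed periods; the ``vertical`` profile
    has a shorter transit path (narrower view) and additionally
    appear/disappear flicker plus a dropout at the start of a return.
    ``clean=True`` omits all failure injections. The seed perturbs
    jitter and failure placement, never the behavior script.
    """
    if angle_profile not in ("horizontal", "vertical"):
        raise ValueError(f"unknown angle profile {angle_profile!r}")
    rng = np.random.default_rng(seed)

    if angle_profile == "horizontal":
        exit_anchor = (480.0, 270.0)
        transit_s = 2.6
    else:
        exit_anchor = (360.0, 202.5)  # shorter radial path: narrower view
        transit_s = 1.6

    segments = (
        (Behavior.ON_BED, 4.0),
        (Behavior.OFF_BED, transit_s),
        (Behavior.NOBODY, 2.0),
        (Behavior.RETURN, transit_s),
        (Behavior.ON_BED, 5.0),
        (Behavior.OFF_BED, transit_s),
        (Behavior.NOBODY, 2.0),
        (Behavior.RETURN, transit_s),
        (Behavior.ON_BED, 4.0),
    )
    base = Scenario(
        segments=segments,
        exit_anchor=exit_anchor,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    if clean:
        return base

    counts = base.segment_frame_counts
    starts = [0]
    for n in counts[:-1]:
        starts.append(starts[-1] + n)

    def jig(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    if angle_profile == "horizontal":
        # dropouts inside on-bed periods (head briefly lost while turning)
        dropouts = (
            (starts[0] + jig(12, 18), jig(3, 6)),
            (starts[0] + jig(33, 38), jig(3, 5)),
            (starts[4] + jig(20, 26), jig(4, 8)),
        )
        flickers: tuple[tuple[int, int], ...] = ()
    else:
        # dropout at the onset of the first return plus flicker bursts
        # during the middle on-bed period; final on-bed period loses the
        # head three times
        dropouts = (
            (starts[3], jig(2, 3)),
            (starts[8] + jig(6, 9), jig(2, 3)),
            (starts[8] + jig(28, 32), jig(3, 4)),
            (starts[8] + jig(48, 52), jig(2, 3)),
        )
        flickers = (
            (starts[4] + jig(10, 14), jig(5, 8)),
            (starts[4] + jig(40, 46), jig(5, 8)),
        )
    return replace(base, dropouts=dropouts, flickers=flickers)
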