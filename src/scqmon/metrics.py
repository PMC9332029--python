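"""Evaluation surface: detection-count metrics and clip-based recognition rates.

Two kinds of numbers are computed. Detection metrics summarize the
object-detection stage from a confusion count (TP, FP, TN, FN):
accuracy A = (TP+TN)/(TP+TN+FP+FN), precision P = TP/(TP+FP), recall
R = TP/(TP+FN) and F1 = 2PR/(P+R). Behavior-recognition rates follow a
clip protocol: ground truth is divided into contiguous single-behavior
clips, and a clip counts as recognized iff at least one event of that
behavior falls inside it; the rate is recognized clips over all clips
of that behavior, with counts summed across sequences before division.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

from .trace_io import Behavior, BehaviorSegment
from .scq import BehaviorEvent


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is zero; it is reported, never silently 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Detection outcome counts; any may be zero."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN) / (TP+TN+FP+FN)."""
    total = c.TP + c.TN + c.FP + c.FN
    if total == 0:
        raise UndefinedMetricError("accuracy undefined for all-zero counts")
    return (c.TP + c.TN) / total


def precision(c: ConfusionCounts) -> float:
    """TP / (TP+FP)."""
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("precision undefined with TP+FP=0")
    return c.TP / (c.TP + c.FP)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP+FN)."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("recall undefined with TP+FN=0")
    return c.TP / (c.TP + c.FN)


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall."""
    p, r = precision(c), recall(c)
    if p + r == 0:
        raise UndefinedMetricError("F1 undefined with P=R=0")
    return 2.0 * p * r / (p + r)


def percent(fraction: float) -> int:
    """Whole-percent rounding with round-half-up (printed-table convention)."""
    return int(
        (Decimal(str(fraction)) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class ClipResult:
    """Per-behavior recognition tally over a set of clips."""

    behavior: Behavior
    n_clips: int
    n_recognized: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_recognized <= self.n_clips):
            raise ValueError("need 0 <= n_recognized <= n_clips")

    @property
    def rate(self) -> float:
        return self.n_recognized / self.n_clips if self.n_clips else 0.0


def protocol_clips(
    segments: Sequence[BehaviorSegment],
) -> tuple[BehaviorSegment, ...]:
    """Convert ground-truth segments into evaluation clips.

    An on-bed period sitting between two transits (a return before it,
    an exit after it) spans two distinct rest episodes and is scored as
    two clips, split at its midpoint. For the canonical two-cycle
    monitoring sequence this yields 4 on-bed, 2 off-bed and 2 return
    clips per sequence. First/last segments and all non-on-bed segments
    pass through unchanged.
    """
    clips: list[BehaviorSegment] = []
    for i, seg in enumerate(segments):
        interior = 0 < i < len(segments) - 1
        if seg.behavior is Behavior.ON_BED and interior and seg.n_frames >= 2:
            mid = seg.start_frame + seg.n_frames // 2
            clips.append(BehaviorSegment(seg.behavior, seg.start_frame, mid - 1))
            clips.append(BehaviorSegment(seg.behavior, mid, seg.end_frame))
        else:
            clips.append(seg)
    return tuple(clips)


def evaluate_clips(
    events: Sequence[BehaviorEvent],
    truth: Sequence[BehaviorSegment],
    max_latency_frames: Optional[int] = None,
) -> tuple[dict[Behavior, ClipResult], dict[tuple[Behavior, Behavior], int]]:
    """Score recognized behaviors against ground-truth clips.

    A clip is credited iff at least one event with the clip's behavior
    falls within its frame range (optionally within
    ``max_latency_frames`` of the clip start — stricter than the
    default any-position accounting). Events of *other* behaviors
    inside a clip are tallied as confusions keyed by
    ``(truth_behavior, event_behavior)``.

    Returns ``(results_by_behavior, confusions)``.
    """
    recognized: dict[Behavior, int] = {}
    totals: dict[Behavior, int] = {}
    confusions: dict[tuple[Behavior, Behavior], int] = {}
    for clip in truth:
        totals[clip.behavior] = totals.get(clip.behavior, 0) + 1
        hit = False
        for e in events:
            if not clip.contains(e.frame_index):
                continue
            if e.behavior == clip.behavior:
                if (
                    max_latency_frames is None
                    or e.frame_index - clip.start_frame <= max_latency_frames
                ):
                    hit = True
            else:
                key = (clip.behavior, e.behavior)
                confusions[key] = confusions.get(key, 0) + 1
        if hit:
            recognized[clip.behavior] = recognized.get(clip.behavior, 0) + 1
    results = {
        b: ClipResult(behavior=b, n_clips=n, n_recognized=recognized.get(b, 0))
        for b, n in totals.items()
    }
    return results, confusions


def batch_evaluate(
    cases: Iterable[tuple[Sequence[BehaviorEvent], Sequence[BehaviorSegment]]],
    max_latency_frames: Optional[int] = None,
) -> dict[Behavior, ClipResult]:
    """Aggregate clip results across sequences: counts are summed
    across cases before the rate is computed."""
    totals: dict[Behavior, list[int]] = {}
    any_case = False
    for events, truth in cases:
        any_case = True
        results, _ = evaluate_clips(events, truth, max_latency_frames)
        for b, r in results.items():
            acc = totals.setdefault(b, [0, 0])
            acc[0] += r.n_clips
            acc[1] += r.n_recognized
    if not any_case:
        raise ValueError("batch_evaluate needs at least one case")
    return {
        b: ClipResult(behavior=b, n_clips=n, n_recognized=k)
        for b, (n, k) in totals.items()
    }
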