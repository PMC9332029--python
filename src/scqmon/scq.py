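"""Status Classification Queueing (SCQ): windowed multi-queue behavior recognition.

Each incoming status is routed to the output queue of its behavior:

====== ========= ==========
status queue     behavior
====== ========= ==========
``+1`` Q1        off bed
``0``  Q2        on bed
``-1`` Q3        return
``-2`` Q4        nobody
====== ========= ==========

The controller keeps at most M = R×T statuses buffered across all
queues (a sliding status window of T seconds at R fps). When the
buffer is full, the globally oldest buffered status is dropped from the
head of its queue before the new one is enqueued — so the buffered
multiset always equals the last M statuses received since the last
flush. The moment a queue reaches its configured length L_j, the
behavior associated with it is emitted and all queues are emptied to
start a new recognition process.

With all L_j = M (the reference operating point: R = 15 fps, T = 1 s,
M = L1..L4 = 15), a behavior fires exactly when the last M statuses
since the flush are uniform, giving a minimum response time of
M / R = 1 second.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Deque, Iterable, Optional, Sequence

from .trace_io import Behavior
from .status import StatusSample

#: Routing of status codes to queue indices 0..3 (Q1..Q4).
STATUS_TO_QUEUE = {1: 0, 0: 1, -1: 2, -2: 3}

#: Behavior recognized when queue j fills (Q1..Q4).
QUEUE_BEHAVIOR = (Behavior.OFF_BED, Behavior.ON_BED, Behavior.RETURN, Behavior.NOBODY)

#: Plot/event encoding: on bed = 0, off bed = 1, return = −1, nobody = 2.
BEHAVIOR_INDEX = {
    Behavior.ON_BED: 0,
    Behavior.OFF_BED: 1,
    Behavior.RETURN: -1,
    Behavior.NOBODY: 2,
}


class SCQConfigError(ValueError):
    """The (R, T, L) configuration violates a window constraint."""


@dataclass(frozen=True)
class SCQConfig:
    """Validated SCQ parameters.

    M = round(R×T) must satisfy M ≤ L1+L2+L3+L4 (the window fits in the
    queues) and M ≥ max(L1..L4) (every queue can actually fill within
    one window). Use :func:`make_config` to build one.
    """

    R: float
    T: float
    M: int
    L: tuple[int, int, int, int]

    @property
    def n_queues(self) -> int:
        return len(self.L)


def make_config(R: float, T: float, L: Sequence[int] = (15, 15, 15, 15)) -> SCQConfig:
    """Build and validate an SCQ configuration.

    Raises :class:`SCQConfigError` naming the violated bound if
    M = round(R×T) exceeds the total queue capacity or is smaller than
    the longest queue.
    """
    if R <= 0 or T <= 0:
        raise SCQConfigError(f"R and T must be positive, got R={R}, T={T}")
    L = tuple(int(x) for x in L)
    if len(L) != 4 or any(x < 1 for x in L):
        raise SCQConfigError(f"need four queue lengths >= 1, got {L}")
    M = max(1, round(R * T))
    if M > sum(L):
        raise SCQConfigError(
            f"M={M} exceeds total queue capacity sum(L)={sum(L)}"
        )
    if M < max(L):
        raise SCQConfigError(f"M={M} is below the longest queue max(L)={max(L)}")
    return SCQConfig(R=R, T=T, M=M, L=L)


@dataclass(frozen=True)
class BehaviorEvent:
    """A recognized behavior, stamped with the frame that completed its queue."""

    behavior: Behavior
    frame_index: int
    time_s: float


@dataclass
class SCQState:
    """Mutable buffer state: four status queues plus global arrival order.

    ``queues[j]`` holds the statuses currently buffered in Q(j+1);
    ``arrival_order`` records which queue each buffered status went to,
    oldest first, so the controller can evict the globally oldest
    status from the head of its queue.
    """

    queues: tuple[Deque[int], Deque[int], Deque[int], Deque[int]] = field(
        default_factory=lambda: (deque(), deque(), deque(), deque())
    )
    arrival_order: Deque[int] = field(default_factory=deque)
    statuses_since_flush: int = 0

    @property
    def total_buffered(self) -> int:
        return len(self.arrival_order)

    def occupancy(self) -> tuple[int, int, int, int]:
        return tuple(len(q) for q in self.queues)  # type: ignore[return-value]

    def flush(self) -> None:
        for q in self.queues:
            q.clear()
        self.arrival_order.clear()
        self.statuses_since_flush = 0


def scq_step(
    state: SCQState, sample: StatusSample, cfg: SCQConfig
) -> Optional[BehaviorEvent]:
    """Feed one status into the SCQ; return the recognized behavior, if any.

    Mutates ``state``. The step is: evict the globally oldest status if
    the buffer already holds M; enqueue the new status at the tail of
    its queue; if that queue now holds L_j statuses, emit the behavior
    of queue j and empty all queues. At most one event can result,
    because only the receiving queue can newly become full.
    """
    try:
        j = STATUS_TO_QUEUE[sample.status]
    except KeyError:
        raise ValueError(f"unknown status value {sample.status}")

    if state.total_buffered == cfg.M:
        oldest_queue = state.arrival_order.popleft()
        state.queues[oldest_queue].popleft()
    state.queues[j].append(sample.status)
    state.arrival_order.append(j)
    state.statuses_since_flush += 1

    if len(state.queues[j]) == cfg.L[j]:
        state.flush()
        return BehaviorEvent(
            behavior=QUEUE_BEHAVIOR[j],
            frame_index=sample.frame_index,
            time_s=sample.time_s,
        )
    return None


def run_scq(
    statuses: Iterable[StatusSample], cfg: SCQConfig
) -> tuple[BehaviorEvent, ...]:
    """Fold :func:`scq_step` over a status stream from the empty state."""
    state = SCQState()
    events: list[BehaviorEvent] = []
    for sample in statuses:
        event = scq_step(state, sample, cfg)
        if event is not None:
            events.append(event)
    return tuple(events)


def dedupe_events(events: Iterable[BehaviorEvent]) -> tuple[BehaviorEvent, ...]:
    """Drop consecutive duplicate behaviors (optional debounce).

    A sustained behavior re-emits every L_j statuses; with debounce only
    the first of each run is kept. Off by default throughout the
    package — the recognition process defines no refractory period.
    """
    out: list[BehaviorEvent] = []
    for e in events:
        if not out or out[-1].behavior != e.behavior:
            out.append(e)
    return tuple(out)


def write_events(events: Iterable[BehaviorEvent], path) -> None:
    """Write recognized events as CSV (behavior, frame, t)."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["behavior", "frame", "t"])
        for e in events:
            writer.writerow([e.behavior.value, e.frame_index, repr(e.time_s)])


def read_events(path) -> tuple[BehaviorEvent, ...]:
    """Read an events CSV written by :func:`write_events`."""
    import csv

    events = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            events.append(
                BehaviorEvent(
                    behavior=Behavior(row["behavior"]),
                    frame_index=int(row["frame"]),
                    time_s=float(row["t"]),
                )
            )
    return tuple(events)


def behavior_index_trace(
    events: Sequence[BehaviorEvent], n_frames: int, initial_index: int = 0
) -> list[int]:
    """Expand events into a per-frame behavior-index step function.

    Each frame carries the index of the most recently emitted behavior
    (on bed = 0, off bed = 1, return = −1, nobody = 2); frames before
    the first event carry ``initial_index`` (default 0, on bed).
    """
    for e in events:
        if e.frame_index >= n_frames:
            raise ValueError(
                f"event at frame {e.frame_index} outside trace of {n_frames} frames"
            )
    out = [initial_index] * n_frames
    current = initial_index
    ev = sorted(events, key=lambda e: e.frame_index)
    k = 0
    for i in range(n_frames):
        while k < len(ev) and ev[k].frame_index == i:
            current = BEHAVIOR_INDEX[ev[k].behavior]
            k += 1
        out[i] = current
    return out
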