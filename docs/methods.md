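# Methods

## Model and assumptions

`scqmon` recognizes bed-related behaviors from a single tracked point
per frame. It assumes: one monitored person; a fixed camera, so pixel
distances are meaningful; a fixed frame rate *R*; and that the
behaviors of interest express themselves as monotone changes of the
distance between the tracked box center and a reference position *P₀*.
It deliberately avoids identity tracking, motion filters and learned
sequence models: the contribution of the method is that a windowed
multi-queue counter over four coarse statuses is enough to be robust to
the detection noise a narrow field of view produces.

**Status classification.** Frame *i*'s status compares
d(*Pᵢ*) = |*PᵢP₀*| with d(*Pᵢ₋₁*): `+1` if d grew by ≥ ε, `−1` if it
shrank by ≥ ε, `0` otherwise, `−2` if the frame has no box. The
Euclidean metric is used because the rule is defined on segment lengths
to *P₀*. Three rules complete the recurrence:

* *Box arbitration*: when a frame holds several boxes the
  first-priority label present wins (default `head` before `trunk` —
  the head is the stable on-bed landmark, the trunk the walking-phase
  one), ties broken by confidence. Status streams are therefore
  invariant to box order within a frame.
* *Dropout carry*: across `−2` gaps the last observed position is
  retained, so a reappearing box is compared against where the person
  was last seen. Resetting instead would misclassify every reappearance
  after a mid-transit dropout.
* *First detection*: with no earlier observation, *P₀* itself stands in
  for the previous position (the monitored person starts stationary
  near the bed in the intended deployment).

**SCQ recognition.** Statuses are routed to four FIFO queues —
Q₁ off bed (`+1`), Q₂ on bed (`0`), Q₃ return (`−1`), Q₄ nobody
(`−2`) — bounded by a global window of M = round(R×T) statuses, valid
when max Lⱼ ≤ M ≤ ΣLⱼ. On each arrival: if M statuses are buffered, the
*globally oldest* is evicted from the head of its queue; the new status
is enqueued; if its queue now holds Lⱼ statuses, behavior *j* is
emitted with the completing sample's frame/time and all queues are
flushed. Global-FIFO eviction is the one reading of "drop from the head
of its output queue" under which the buffer is exactly the last
min(M, since-flush) statuses — the property the test suite pins against
a brute-force list-slicing oracle at every step. Evict-then-insert-
then-check order, and identical flush handling for all four behaviors,
are fixed by those same oracle tests. The queue-occupancy formulation
is used rather than the per-behavior sum identities (ΣŜ = L₁ for off
bed, Σ(1−Ŝ) = L₂ for on bed, Σ(−Ŝ) = L₃ for return, Σ(−Ŝ/2) = L₄ for
nobody), which admit unintended mixed-status solutions when M > Lⱼ; in
the pure-window case M = Lⱼ the two coincide, which is asserted in the
tests. A sustained behavior re-emits every Lⱼ statuses; an optional
debounce collapses consecutive duplicates but is off by default since
the recognition process defines no refractory period.

## Parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| R | fps | 15 | commodity bed-side camera rate |
| T | s | 1.0 | alarm-relevant response time; M = 15 |
| L₁…L₄ | statuses | 15 each | uniform sensitivity; minimum latency Lⱼ/R = 1 s |
| ε | px | 5 | at 640×360: ~1.4 % of the image diagonal — above detector jitter (~1 px), far below transit motion (12 px/frame at defaults) |
| P₀ mode | — | origin | parameter-free; fixed bed anchor and first-detection modes are supported |

Shorter Lⱼ make behavior *j* fire faster and more eagerly; M couples
them by bounding how much history any queue can accumulate.

## Synthetic scenarios

The generator scripts (behavior, duration) segments and renders them:
on-bed frames are the bed anchor plus Gaussian jitter (σ = 1 px);
exits/returns are linear transits between bed and exit anchors at 180
px/s (12 px/frame at 15 fps), the label switching head↔trunk at the
transit midpoint; nobody segments are boxless. Both anchors are
collinear with the image origin so that transit motion is purely radial
with respect to the default *P₀*. Failure modes: *dropouts* blank a
window of frames, *flicker* blanks alternate frames of a window, and
*turn-over bursts* (on by default) occasionally triple the on-bed
jitter, clipped to 2.25 px so a genuine rest period cannot cross ε.
Box sizes (head 40×40, trunk 80×120) and confidences (U(0.6, 0.99))
are cosmetic: statuses depend only on centers, confidences only matter
for arbitration order. All randomness flows from one seed;
`two_cycle_scenario` builds the canonical nine-segment two-cycle
script (on, off, nobody, return, ×2, ending on), with per-profile
transit lengths (horizontal 367 px, vertical 230 px — the narrower
vertical view) and failure placements: horizontal puts multi-frame
dropouts inside on-bed periods; vertical adds a dropout at a return
onset and flicker bursts. Dropout and flicker durations (2–8 frames)
are stated configuration, not estimates from data: real
narrow-field-of-view failure statistics are not quantified anywhere we
can recompute from.

What passing synthetic tests shows: the *recognition* stages behave
exactly as specified under the modeled noise. What it does not show:
performance under real detector error statistics, multiple people,
camera motion, or behaviors outside the four-way taxonomy.

## Evaluation protocol

Ground truth is divided into single-behavior clips; a clip is
recognized iff at least one event of its behavior falls inside it (any
position — the binary per-clip accounting; a `max_latency_frames`
option tightens this for stress tests), and events of other behaviors
inside a clip are tallied as confusions. `protocol_clips` scores an
interior on-bed period (between a return and the next exit) as two
clips split at its midpoint, since it spans two rest episodes; a
two-cycle sequence therefore contributes 4 on-bed, 2 off-bed and 2
return clips, and counts are summed across sequences before rates are
computed. Detection metrics are the standard confusion-count forms;
zero denominators raise rather than silently returning 0, and
whole-percent reporting uses round-half-up to match printed-table
convention.

## Numerical choices and degenerate inputs

* M rounds to nearest, floor 1; uF = round(W×R), floor 1.
* Status thresholds use ≥ ε (ties classify as motion).
* Floats are serialized with `repr`, so file round-trips are exact.
* Empty traces classify to empty streams and produce no events; an
  all-empty trace with `p0_mode="first_detection"` is an error naming
  the condition.
* Undefined metrics (zero denominators) raise `UndefinedMetricError`.

## Problem sizes

The test suite and acceptance script use ten simulated sequences per
camera profile (~410 frames each, ≈27 s of video), 10⁴ random status
streams of 40–50 statuses for the window-equivalence oracle, and the
published raw detection counts for the metric reproductions; the whole
acceptance run completes in seconds.

## Known limitations

Single-person scenes only; no re-identification after long absences
(a visitor sitting on the bed is "on bed"); ε and the anchors are
resolution-dependent and must be rescaled for other image sizes;
recognition latency is bounded below by Lⱼ/R, so faster alarms require
shorter queues at the cost of noise sensitivity; the simulator's
linear-transit trajectories are simpler than real gait paths — it
reproduces status patterns, not pixel kinematics.
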