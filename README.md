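# scqmon

Bed-exit behavior recognition from bounding-box detection streams.

Falls are a leading hazard for hospitalized and elderly patients, and
most happen when someone leaves the bed unattended. A bed-side camera
with a narrow field of view keeps the scene simple and private, but its
object detector loses the patient often: boxes drop out for a few
frames, flicker on and off, and jump abruptly when the patient turns
over. `scqmon` implements a deliberately lightweight recognizer that
converts such a lossy per-frame detection stream into discrete
bed-related behavior events — **on bed**, **off bed**, **return**,
**nobody** — robustly and with a bounded response time, with no
tracking filter or learned sequence model.

## Method

Each frame *i* is first reduced to an activity status by comparing the
tracked box center *Pᵢ* against a reference position *P₀* (the image
origin or a bed-anchored point), with distance threshold ε:

```
Ŝ = +1  if |PᵢP₀| − |Pᵢ₋₁P₀| ≥ ε      (moving away from the bed)
     0  if ||PᵢP₀| − |Pᵢ₋₁P₀|| < ε     (neutral)
    −1  if |Pᵢ₋₁P₀| − |PᵢP₀| ≥ ε      (moving toward the bed)
    −2  if no bounding box
```

Statuses then enter the **Status Classification Queueing (SCQ)**
buffer: four FIFO queues Q₁…Q₄ (off bed, on bed, return, nobody), one
per status, under a global window of

```
M = R × T,   subject to  M ≤ ΣLⱼ  and  M ≥ max Lⱼ
```

statuses (*R* fps, time slot *T* seconds, queue lengths *Lⱼ*). When the
buffer is full the globally oldest status is dropped from the head of
its queue, so the buffered multiset is always the last *M* statuses.
The moment queue *j* holds *Lⱼ* statuses its behavior is emitted and
all queues are flushed. Statuses caused by isolated dropouts or jitter
land in other queues and age out of the window instead of corrupting
the decision — that is the entire robustness mechanism. At the default
operating point (*R* = 15, *T* = 1 s, all *Lⱼ* = 15) the minimum
response time is exactly one second.

The package also provides a seeded scenario simulator emulating
narrow-field-of-view failure phenomenology (dropouts, flicker, on-bed
jitter bursts), the clip-based recognition-rate protocol and the
detection metrics (accuracy, precision, recall, F1), so the full
pipeline is testable without a camera.

## Worked example

```python
from scqmon import classify_trace, generate, make_config, two_cycle_scenario, run_scq

case = generate(two_cycle_scenario("horizontal", seed=1))   # 411 frames, 15 fps
cfg = make_config(R=15, T=1.0, L=(15, 15, 15, 15))           # M = 15
events = run_scq(classify_trace(case.trace), cfg)
for e in events[:5]:
    print(f"{e.behavior.value:8s} recognized at frame {e.frame_index:4d} (t = {e.time_s:6.2f} s)")
```

prints

```
on_bed   recognized at frame   35 (t =   2.33 s)
on_bed   recognized at frame   55 (t =   3.67 s)
off_bed  recognized at frame   74 (t =   4.93 s)
off_bed  recognized at frame   89 (t =   5.93 s)
nobody   recognized at frame  113 (t =   7.53 s)
```

The simulated patient lies on the bed for four seconds; the first
on-bed event lands at 2.33 s rather than 1.0 s because an injected
6-frame detection dropout interrupts the first window — the dropout
statuses go to the *nobody* queue, age out, and never produce a false
alarm. The exit transit then fills the off-bed queue within a second of
sustained outward motion. `examples/` contains one short script per
capability (simulation, status classification, recognition, the clip
protocol, detection metrics), and the same pipeline is scriptable from
the shell:

```sh
scqmon simulate --profile horizontal --seed 1 --out-dir run1
scqmon run run1/trace.jsonl --out-dir run1
scqmon evaluate run1/events.csv run1/truth.csv --out-dir run1
```

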