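"""Per-frame status classification of an exit transit.

A status compares each frame's distance to the reference position P0
against the previous frame's: +1 moving away, -1 moving toward,
0 neutral (change below epsilon), -2 no detection.
"""

from collections import Counter

from scqmon import Behavior, ClassifierConfig, Scenario, classify_trace, generate

scenario = Scenario(
    segments=((Behavior.ON_BED, 1.0), (Behavior.OFF_BED, 2.0), (Behavior.NOBODY, 1.0)),
    seed=3,
)
samples = classify_trace(generate(scenario).trace, ClassifierConfig(epsilon=5.0))

counts = Counter(s.status for s in samples)
print("status counts over", len(samples), "frames:", dict(counts))
print("first 40 statuses:", [s.status for s in samples[:40]])
# Expect mostly 0 while on the bed, a run of +1 during the exit transit
# (12 px per frame against epsilon = 5 px), and -2 once nobody is visible.
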