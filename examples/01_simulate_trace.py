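"""Simulate a narrow-field-of-view monitoring sequence.

Builds the canonical two-cycle scenario (lie on bed, exit, gone,
return — twice — ending on the bed), renders it into a detection trace
with seeded jitter and dropout injections, and prints its shape.
"""

from scqmon import generate, two_cycle_scenario

scenario = two_cycle_scenario("horizontal", seed=1)
case = generate(scenario)

print(f"frames: {len(case.trace)} at {case.trace.frame_rate:g} fps")
print(f"dropout windows (start, length): {scenario.dropouts}")
print("ground-truth segments:")
for seg in case.truth:
    print(f"  {seg.behavior.value:8s} frames {seg.start_frame:4d}-{seg.end_frame:4d}")
empty = sum(1 for f in case.trace if not f.boxes)
print(f"frames without a detection: {empty}")
# The empty frames come from the two 'nobody' segments plus the injected
# dropouts; everything else carries one head or trunk box with jitter.
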