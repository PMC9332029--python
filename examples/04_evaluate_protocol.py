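"""Clip-based recognition rates over ten monitoring sequences.

Each sequence contributes 4 on-bed, 2 off-bed and 2 return clips
(interior on-bed periods are scored as two rest episodes); a clip
counts as recognized iff an event of its behavior falls inside it.
"""

from scqmon import batch_evaluate, generate, two_cycle_scenario, protocol_clips
from scqmon.cli import run_pipeline

cases = [generate(two_cycle_scenario("horizontal", seed=s)) for s in range(10)]
results = batch_evaluate(
    (run_pipeline(c.trace)[1], protocol_clips(c.truth)) for c in cases
)
for b, r in sorted(results.items(), key=lambda kv: kv[0].value):
    print(f"{b.value:8s} {r.n_recognized:3d}/{r.n_clips:<3d} = {100 * r.rate:.0f}%")
# With default parameters every clip is recognized (100%), including
# sequences carrying injected multi-frame detection dropouts.
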