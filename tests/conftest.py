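import random

import pytest

from scqmon import (
    Behavior,
    BoundingBox,
    DetectionTrace,
    FrameDetection,
    Scenario,
)


def random_trace(rng: random.Random, n_frames: int = 20, R: float = 15.0) -> DetectionTrace:
    """A seeded arbitrary-but-valid trace for round-trip properties."""
    frames = []
    t = 0.0
    for i in range(n_frames):
        boxes = []
        for _ in range(rng.randint(0, 3)):
            boxes.append(
                BoundingBox(
                    label=rng.choice(["head", "trunk"]),
                    cx=rng.uniform(-1e3, 1e3),
                    cy=rng.uniform(-1e3, 1e3),
                    w=rng.uniform(1e-3, 500.0),
                    h=rng.uniform(1e-3, 500.0),
                    conf=rng.random(),
                )
            )
        frames.append(FrameDetection(frame_index=i, time_s=t, boxes=tuple(boxes)))
        t += rng.uniform(0.0, 0.2)
    return DetectionTrace(frames=tuple(frames), frame_rate=R)


@pytest.fixture
def rng():
    return random.Random(20260925)


@pytest.fixture
def single_segment_scenario():
    def make(behavior: Behavior, duration_s: float, **kwargs) -> Scenario:
        return Scenario(segments=((behavior, duration_s),), **kwargs)

    return make
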