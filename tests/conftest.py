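import numpy as np
import pytest

from penwatch.detections import Detection
from penwatch.geometry import BoundingBox
from penwatch.simulator import PenConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """10 pigs, 120 noise-free frames — shared across modules."""
    return simulate(PenConfig(n_pigs=10, seed=7), 120)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, max_xy=300, max_wh=80) -> BoundingBox:
    return BoundingBox(
        x=float(rng.integers(0, max_xy)),
        y=float(rng.integers(0, max_xy)),
        width=float(rng.integers(1, max_wh)),
        height=float(rng.integers(1, max_wh)),
    )


def gt_records(sim):
    """Identity-carrying ground-truth records for tracking evaluation."""
    return [
        (a.gt_id, Detection(frame=a.frame, box=a.box, cls=a.cls, score=1.0))
        for a in sim.annotations
    ]


def perfect_detections(sim):
    return [
        Detection(frame=a.frame, box=a.box, cls=a.cls, score=1.0)
        for a in sim.annotations
    ]
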