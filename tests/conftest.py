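import numpy as np
import pytest

from mocapfill import (
    MotionSequence,
    SyntheticSkeletonConfig,
    generate_synthetic_sequence,
)


@pytest.fixture(scope="session")
def short_seq() -> MotionSequence:
    """10 s of the default 41-marker humanoid with 0.5 mm noise."""
    return generate_synthetic_sequence(SyntheticSkeletonConfig(duration_s=10.0), seed=7)


@pytest.fixture(scope="session")
def noiseless_seq() -> MotionSequence:
    """10 s, noiseless: rigid-body distances are exactly constant."""
    cfg = SyntheticSkeletonConfig(duration_s=10.0, noise_std_mm=0.0)
    return generate_synthetic_sequence(cfg, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def mask_gap(seq: MotionSequence, marker: int, start: int, stop: int) -> MotionSequence:
    """Return a copy with frames [start, stop) of one marker masked out."""
    out = seq.copy()
    out.mask[start:stop, marker] = False
    out.positions[start:stop, marker, :] = np.nan
    return out


@pytest.fixture()
def make_gapped():
    return mask_gap
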