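import numpy as np
import pytest

from tcdasym.hemodynamics import Side, VelocitySample


@pytest.fixture
def four_sample_patient() -> list[VelocitySample]:
    """One in-window measurement per side x segment, hand-checkable."""
    return [
        VelocitySample(psv=90, edv=45, depth=60, side=Side.RIGHT),
        VelocitySample(psv=84, edv=42, depth=50, side=Side.RIGHT),
        VelocitySample(psv=75, edv=45, depth=60, side=Side.LEFT),
        VelocitySample(psv=72, edv=42, depth=50, side=Side.LEFT),
    ]


@pytest.fixture
def symmetric_patient() -> list[VelocitySample]:
    return [
        VelocitySample(psv=90, edv=45, depth=60, side=Side.RIGHT),
        VelocitySample(psv=84, edv=42, depth=50, side=Side.RIGHT),
        VelocitySample(psv=90, edv=45, depth=60, side=Side.LEFT),
        VelocitySample(psv=84, edv=42, depth=50, side=Side.LEFT),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260906)
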