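import numpy as np
import pytest

from leafletseg.encoding import FrameMode, InputConfig, assemble_stack
from leafletseg.phantom import PhantomSpec, make_phantom
from leafletseg.preprocess import ResamplePlan, build_valve_frame, resample_case


@pytest.fixture(scope="session")
def phantom_case():
    """One default phantom shared across tests (read-only)."""
    return make_phantom(seed=7)


@pytest.fixture(scope="session")
def desk_case(phantom_case):
    """The phantom reoriented into a 48^3 desk-scale ROI with its stack."""
    xf = build_valve_frame(phantom_case.annotation)
    plan = ResamplePlan(spacing_mm=0.55, transform=xf, roi_shape=(48, 48, 48))
    seq, gt, ann = resample_case(
        phantom_case.sequence, phantom_case.gt, phantom_case.annotation, plan
    )
    stack = assemble_stack((seq, ann), InputConfig(FrameMode.SINGLE, True, True, True))
    return seq, gt, ann, stack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
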