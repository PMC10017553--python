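import numpy as np
import pytest

from zfvision.protocols import AssayProtocol, LightEpoch
from zfvision.tracking_io import SpeedTrace


@pytest.fixture
def short_vmr() -> AssayProtocol:
    """A desk-scale VMR-like schedule: 2 min dark, then 2 x (1 min ON, 1 min OFF)."""
    return AssayProtocol(
        "vmr",
        (
            LightEpoch(0, 120, 0),
            LightEpoch(120, 60, 30),
            LightEpoch(180, 60, 0),
            LightEpoch(240, 60, 30),
            LightEpoch(300, 60, 0),
        ),
        bin_s=1.0,
    )


@pytest.fixture
def constant_light() -> AssayProtocol:
    return AssayProtocol(
        "freeswim_light",
        (LightEpoch(0, 60, 30),),
        bin_s=10.0,
        adaptation_intensity_pct=30,
    )


def make_trace(speeds, frame_dt_s=0.1, well_id="W001", genotype="WT", batch="b1"):
    return SpeedTrace(
        well_id=well_id,
        genotype=genotype,
        batch=batch,
        frame_dt_s=frame_dt_s,
        speeds=np.asarray(speeds, dtype=float),
    )


@pytest.fixture
def trace_factory():
    return make_trace
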