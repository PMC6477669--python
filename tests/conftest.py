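import numpy as np
import pytest

from padmech import (
    DEFAULT_GEOMETRY,
    StressStretchCurve,
    load_reference_parameters,
    uniaxial_stress,
)


@pytest.fixture(scope="session")
def ref_params():
    """Packaged per-rate Yeoh parameter sets."""
    return load_reference_parameters()


@pytest.fixture(scope="session")
def control_params(ref_params):
    return ref_params["control-1.96"]


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture
def control_curve(control_params):
    """Noise-free 50-point stress-stretch curve from the control plant."""
    lam = np.linspace(0.55, 1.0, 50)
    return StressStretchCurve(
        stretch=lam, stress=uniaxial_stress(lam, control_params)
    )
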