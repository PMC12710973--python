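import numpy as np
import pytest

from mechanomap import (
    DEFAULT_MODEL,
    detect_particles,
    filter_aggregates,
    generate_calibration_phantom,
)


@pytest.fixture(scope="session")
def model():
    return DEFAULT_MODEL


@pytest.fixture(scope="session")
def zero_stress_phantom():
    """A default-noise, zero-stress 30-particle phantom (seeded)."""
    volume, scene = generate_calibration_phantom(30, 0.0, seed=42)
    return volume, scene


@pytest.fixture(scope="session")
def reference_sbr0(zero_stress_phantom):
    """Cohort-mean SBR of unstressed sensors, measured by the detector."""
    volume, _ = zero_stress_phantom
    retained, _ = filter_aggregates(detect_particles(volume))
    return float(np.mean([d.sbr for d in retained]))
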