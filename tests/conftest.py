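import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings
    settings.register_profile(
        "suite", deadline=None, derandomize=True, max_examples=50,
        suppress_health_check=[HealthCheck.too_slow])
    settings.load_profile("suite")
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass

from mechanoephys.mechanics import ForceCurve
from mechanoephys.synthetic import SynthConfig


@pytest.fixture
def default_config():
    return SynthConfig(seed=0)


def make_curve(z, deflection, segment=None, k=0.02, R=2.5, speed=10.0,
               timestamp=0.0, fs=2000.0):
    """Assemble a ForceCurve from height/deflection arrays (approach-only
    unless a segment array is given)."""
    z = np.asarray(z, dtype=float)
    d = np.asarray(deflection, dtype=float)
    if segment is None:
        segment = np.array(["approach"] * z.size, dtype=object)
    t = np.arange(z.size) / fs
    return ForceCurve(time=t, height=z, deflection=d, segment=segment,
                      spring_constant=k, bead_radius=R, speed=speed,
                      timestamp=timestamp)
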