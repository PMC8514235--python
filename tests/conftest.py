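import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retinotype.core import FieldGeometry, TrialResponse
from retinotype.morpho import Arbor

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def square_mm() -> FieldGeometry:
    """A 1 mm² field."""
    return FieldGeometry(1000.0, 1000.0)


@pytest.fixture
def path_arbor() -> Arbor:
    """A straight 100 µm dendrite from the soma along +y, in 10 µm steps."""
    n = 11
    xyz = np.zeros((n, 3))
    xyz[:, 1] = 10.0 * np.arange(n)
    return Arbor(xyz, np.full(n, 0.5), np.arange(-1, n - 1))


@pytest.fixture
def y_tree() -> Arbor:
    """Stem (0,0,0)->(0,50,0), children to (±30,90,0): three 50 µm segments."""
    xyz = np.array(
        [[0, 0, 0], [0, 50, 0], [30, 90, 0], [-30, 90, 0]], dtype=float
    )
    return Arbor(xyz, np.full(4, 0.5), np.array([-1, 0, 1, 1]))


@pytest.fixture
def step_current() -> TrialResponse:
    """10 pA above a zero baseline for 0.5 s, sampled at 10 kHz."""
    from retinotype.synthetic import generate_current_trace

    return generate_current_trace(
        epochs={"baseline": (0.0, 0.5), "stim": (0.5, 1.0)},
        amplitudes={"stim": 10.0},
        baseline=0.0,
        noise_sd=0.0,
    )


def make_trace(values, sample_rate=10.0, epochs=None) -> TrialResponse:
    return TrialResponse(np.asarray(values, dtype=float), sample_rate, epochs or {})
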