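import numpy as np
import pytest

from muellercal import (
    PerturbationSpec,
    nominal_instrument,
    perturb_instrument,
)
from muellercal.mueller_models import DichroicRetarderSpec, dr_mueller3


@pytest.fixture(scope="session")
def nominal4():
    return nominal_instrument("four_state")


@pytest.fixture(scope="session")
def nominal3():
    return nominal_instrument("three_state")


@pytest.fixture(scope="session")
def perturbed_truth(nominal4):
    """A reproducible imperfect instrument: the ground truth to recover."""
    spec = PerturbationSpec(
        angle_sigma=1.0,
        q_range=(0.85, 1.0),
        r_range=(0.0, 0.02),
        source_dop=0.03,
        source_azimuth=30.0,
    )
    return perturb_instrument(nominal4, spec, rng=7)


@pytest.fixture(scope="session")
def realistic_lp_set():
    """Four finite-extinction LP calibration samples near 0/45/90/135 deg."""
    return [
        DichroicRetarderSpec(0.0, 0.98, 0.004, 0.0),
        DichroicRetarderSpec(44.0, 0.97, 0.005, 0.0),
        DichroicRetarderSpec(91.0, 0.99, 0.003, 0.0),
        DichroicRetarderSpec(136.0, 0.96, 0.006, 0.0),
    ]


def random_dr_specs(n, rng, delta_range=(0.0, 180.0)):
    """Random valid dichroic-retarder specs for property-style sweeps."""
    out = []
    for _ in range(n):
        q = rng.uniform(0.05, 1.0)
        r = rng.uniform(0.0, q)
        out.append(
            DichroicRetarderSpec(
                rng.uniform(0.0, 180.0), q, r, rng.uniform(*delta_range)
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def measure_set(instrument, specs):
    """Air + sample intensity matrices for a list of DR specs (noiseless)."""
    from muellercal import simulate_measurement

    air = instrument.air_measurement()
    P = [simulate_measurement(instrument, dr_mueller3(s)) for s in specs]
    return air, P
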