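import numpy as np
import pytest

from ironpbpk import (
    DoseEvent,
    KineticParameters,
    load_parameters,
    load_physiology,
)

MOUSE_SAMPLING = (0.25, 12.0, 24.0, 96.0, 168.0, 336.0, 672.0)


@pytest.fixture(scope="session")
def mouse_phys():
    return load_physiology("mouse")


@pytest.fixture(scope="session", params=["iron_deficient", "iron_adequate", "iron_loaded"])
def diet(request):
    return request.param


@pytest.fixture(scope="session")
def diet_params(diet):
    return load_parameters(f"mouse_{diet}")


@pytest.fixture
def tracer_dose(mouse_phys):
    """The standard radiotracer bolus: 0.2 umol/kg in a 25 g mouse."""
    return DoseEvent(time=0.0, amount=0.2 * mouse_phys.body_weight)


def random_admissible_params(phys, rng: np.random.Generator) -> KineticParameters:
    """A physiologically plausible random parameter draw (KP in 0.05-50)."""
    kp = {o: float(np.exp(rng.uniform(np.log(0.05), np.log(50.0))))
          for o in phys.organ_names}
    return KineticParameters(
        kp=kp,
        cl_loss=float(rng.uniform(0.0, 1e-3)),
        q_e=float(rng.uniform(1e-5, 1e-2)),
        t_rbc=float(rng.uniform(20.0, 500.0)),
    )
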