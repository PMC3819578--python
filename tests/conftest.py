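import numpy as np
import pytest

from pibtransfer import (
    FrameSchedule,
    PlasmaCurve,
    TissueKineticTruth,
    default_parent_params,
    default_pib_aif_params,
    default_water_aif_params,
    pib_frame_schedule,
    simulate_aif,
    water_frame_schedule,
)
from pibtransfer.synthetic import pib_sampling_times, water_sampling_times


@pytest.fixture(scope="session")
def pib_plasma():
    """Default triphasic PiB arterial curve with parent-fraction samples."""
    return simulate_aif(
        default_pib_aif_params(), pib_sampling_times(), "PiB", default_parent_params()
    )


@pytest.fixture(scope="session")
def pib_input(pib_plasma):
    """Metabolite-corrected input that drives tissue uptake."""
    return pib_plasma.parent_corrected()


@pytest.fixture(scope="session")
def pib_frames():
    return pib_frame_schedule()


@pytest.fixture(scope="session")
def water_blood():
    return simulate_aif(default_water_aif_params(), water_sampling_times(), "water")


@pytest.fixture(scope="session")
def water_frames():
    return water_frame_schedule()


@pytest.fixture(scope="session")
def constant_plasma():
    """Constant unit input over 20 min: every Patlak quantity is closed-form."""
    t = np.arange(0.0, 20.0 + 1e-9, 0.05)
    return PlasmaCurve(times=t, activity=np.ones_like(t))


@pytest.fixture(scope="session")
def constant_frames():
    return FrameSchedule.from_durations([0.5] * 40)


@pytest.fixture(scope="session")
def pib_truth():
    """One-tissue truth used throughout: K1 = 0.28 mL/g/min, Vg = 2 mL/cm^3."""
    return TissueKineticTruth(K1=0.28, k2=0.14, Vo=0.05)
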