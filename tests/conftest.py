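import numpy as np
import pytest

import vasomech as vm


@pytest.fixture(scope="session")
def geom():
    return vm.PRESET_GEOMETRY


@pytest.fixture(scope="session")
def compliant():
    return vm.preset("compliant")


@pytest.fixture(scope="session")
def stiff():
    return vm.preset("stiff")


@pytest.fixture(scope="session")
def physiological_drive():
    """80/120 mmHg pulsatile drive, 65 beats/min, 30 s at 50 Hz."""
    return vm.generate_pulsatile_pressure(
        vm.PulseSpec(80.0, 120.0, 65.0, 30.0, 50.0)
    )


@pytest.fixture(scope="session")
def compliant_recording(compliant, geom, physiological_drive):
    """Noise-free pulsatile recording of the compliant preset."""
    return vm.simulate_recording(compliant, geom, physiological_drive)


@pytest.fixture(scope="session")
def stiff_recording(stiff, geom, physiological_drive):
    return vm.simulate_recording(stiff, geom, physiological_drive)
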