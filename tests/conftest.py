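import numpy as np
import pytest

from radialasl.protocol import AcquisitionProtocol


def nrmse(x, ref):
    return float(np.linalg.norm(x - ref) / np.linalg.norm(ref))


@pytest.fixture(scope="session")
def protocol_full():
    """Full-scale 48-pair protocol (Table-1-like timing)."""
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def protocol_desk():
    """Desk-scale protocol used for simulation/reconstruction tests."""
    return AcquisitionProtocol.preset_desk()


@pytest.fixture(scope="session")
def desk_pipeline():
    """One noisy desk-scale end-to-end run shared by the reconstruction
    benchmark and the integration tests (expensive: several minutes)."""
    from radialasl.pipeline import run_pipeline
    return run_pipeline(seed=0, snr=20.0)
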