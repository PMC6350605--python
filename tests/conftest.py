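import numpy as np
import pytest

from glucopred import GlycemiaParams
from glucopred.virtual_patient import NoiseSpec, VirtualPatientSpec, generate_log

#: multipliers planted on (K_xgi, K_xi, V_I) for the recovery tests —
#: all three sit exactly on the default brute-force grid
PLANTED = {"K_xgi": 0.8, "K_xi": 1.2, "V_I": 1.0}


@pytest.fixture(scope="session")
def ref_params():
    return GlycemiaParams(body_weight_kg=80.0)


@pytest.fixture(scope="session")
def planted_patient_noisefree():
    """3-day noise-free virtual patient with known planted multipliers."""
    spec = VirtualPatientSpec(multipliers=dict(PLANTED), noise=NoiseSpec.none(), seed=1)
    log, truth = generate_log(spec, days=3)
    return spec, log, truth


@pytest.fixture(scope="session")
def planted_patient_noisy():
    """Same planted patient under the default CGMS noise model."""
    spec = VirtualPatientSpec(multipliers=dict(PLANTED), seed=1)
    log, truth = generate_log(spec, days=3)
    return spec, log, truth


@pytest.fixture(scope="session")
def reference_patient_noisy():
    """3-day reference-parameter patient with default noise."""
    spec = VirtualPatientSpec(seed=3)
    log, truth = generate_log(spec, days=3)
    return spec, log, truth


@pytest.fixture(scope="session")
def short_log_noisefree():
    """1-day noise-free log for cheap unit tests."""
    spec = VirtualPatientSpec(noise=NoiseSpec.none(), seed=4)
    log, truth = generate_log(spec, days=1)
    return log, truth
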