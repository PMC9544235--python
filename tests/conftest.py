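"""Shared fixtures: protocols and one reusable phantom session per scope."""

import pytest

from lungdce import AcquisitionProtocol
from lungdce.phantom import (default_noise_sd, make_phantom_geometry,
                             population_aif, simulate_acquisition)


@pytest.fixture(scope="session")
def protocol():
    """Printed whole-chest protocol with single-shot VFA (fast tests)."""
    return AcquisitionProtocol(vfa_repeats=1)


@pytest.fixture(scope="session")
def protocol_repeats():
    """Full protocol including the 10 VFA repeats per angle."""
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def noiseless_session(protocol):
    """One noiseless HV-like phantom acquisition shared across tests."""
    regions, gt = make_phantom_geometry((20, 20, 10), group="hv", seed=11)
    aif = population_aif(protocol)
    vfa, dyn = simulate_acquisition(gt, aif, protocol, regions,
                                    noise_sd=0.0, seed=0)
    return {"regions": regions, "gt": gt, "aif": aif, "vfa": vfa, "dyn": dyn,
            "protocol": protocol}


@pytest.fixture(scope="session")
def noisy_session(protocol_repeats):
    """Default-noise (SNR 50, Rician) HV-like phantom acquisition."""
    p = protocol_repeats
    regions, gt = make_phantom_geometry((20, 20, 10), group="hv", seed=13)
    sd = default_noise_sd(gt, regions, p, snr=50.0)
    aif = population_aif(p)
    vfa, dyn = simulate_acquisition(gt, aif, p, regions, noise_sd=sd, seed=5)
    return {"regions": regions, "gt": gt, "aif": aif, "vfa": vfa, "dyn": dyn,
            "protocol": p, "noise_sd": sd}
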