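import numpy as np
import pytest

from faplate import (
    PlateDesign,
    SimulationTruth,
    dilution_series,
    get_peptide,
    simulate_plate,
)


@pytest.fixture(scope="session")
def design() -> PlateDesign:
    return PlateDesign()


@pytest.fixture(scope="session")
def cam_series(design) -> np.ndarray:
    return dilution_series(design)


@pytest.fixture(scope="session")
def noiseless_plate(design):
    truth = SimulationTruth(kd_apo=100e-9, kd_sat=100e-9,
                            noise_sd=0.0, pipette_cv=0.0)
    return simulate_plate(design, truth)


@pytest.fixture(scope="session")
def default_plate(design):
    return simulate_plate(design, SimulationTruth(seed=42))


@pytest.fixture(scope="session")
def null_design():
    return PlateDesign(peptide=get_peptide("null_probe"))
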