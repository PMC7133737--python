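import numpy as np
import pytest

import pbpkit as pk


@pytest.fixture(scope="session")
def mouse_physiology():
    return pk.get_species_physiology("mouse")


@pytest.fixture(scope="session")
def human_physiology():
    return pk.get_species_physiology("human")


@pytest.fixture(scope="session")
def at_rvd1():
    return pk.get_compound("at_rvd1", fu_plasma=0.05)


@pytest.fixture(scope="session")
def mouse_clearance():
    return pk.ClearanceSpec(mode="calibrated_total", total_plasma_clearance_ml_min_kg=4.58)


@pytest.fixture(scope="session")
def mouse_model(mouse_physiology, at_rvd1, mouse_clearance):
    return pk.build_model(mouse_physiology, at_rvd1, mouse_clearance)


@pytest.fixture(scope="session")
def fast_one_compartment():
    """One-compartment reduction with a 1-hr half-life (cheap to simulate).

    V = 1 L/kg and CL chosen so ke = ln2/hr.
    """
    cl_ml_min_kg = 1000.0 * np.log(2.0) / 60.0
    model, ke = pk.one_compartment_inputs(1.0, cl_ml_min_kg)
    return model, ke, cl_ml_min_kg


@pytest.fixture(scope="session")
def fine_short_grid():
    """Grid resolving the venous mixing spike, for accurate AUC on toys."""
    return np.concatenate(
        [[0.0], np.geomspace(1e-8, 0.1, 100), np.arange(0.2, 10.01, 0.1)]
    )
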