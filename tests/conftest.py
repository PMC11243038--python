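import numpy as np
import pytest

from rrsolv import default_solute, make_chromophore, make_solvated_frame


@pytest.fixture(scope="session")
def solute():
    return default_solute()


@pytest.fixture(scope="session")
def planted_frame(solute):
    """50 waters, one planted H-bond water at each acceptor site."""
    return make_solvated_frame(
        solute, 50, 17.0, {"N9": 1, "O10": 1, "O12": 1}, 2.4, seed=2)


@pytest.fixture()
def single_mode_model():
    """One-mode chromophore with Delta = 1 (S = 0.5) at 1400 cm⁻¹."""
    return make_chromophore(
        3, 1, n_states=1, seed=11, displacements=np.array([[1.0]]),
        freqs_cm=[1400.0], state_energies_cm=[40000.0], osc_strengths=[0.3])


@pytest.fixture()
def three_mode_model():
    return make_chromophore(
        5, 3, n_states=1, seed=4, displacements=np.array([[0.5, -0.8, 0.3]]),
        state_energies_cm=[39000.0], osc_strengths=[0.3])
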