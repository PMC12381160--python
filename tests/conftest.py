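import numpy as np
import pytest

from chirsep.electronic_weights import SurrogateProvider
from chirsep.structures_io import Molecule3D, SaltComplex
from chirsep.synthetic import ToyChiralSpec, build_agent, make_chiral_complex


@pytest.fixture
def provider():
    return SurrogateProvider()


@pytest.fixture
def water():
    return Molecule3D(
        ["O", "H", "H"],
        np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]),
    )


@pytest.fixture
def tiny_complex():
    """A 5-atom acid-base complex, small enough for brute-force oracles."""
    sub = Molecule3D(
        ["C", "O", "H"],
        np.array([[0.0, 0.0, 0.0], [1.2, 0.3, -0.1], [1.9, -0.5, 0.6]]),
        role="substrate",
    )
    agt = Molecule3D(
        ["N", "H"],
        np.array([[3.1, 0.2, 0.4], [3.8, 0.9, 0.1]]),
        role="resolving_agent",
    )
    return SaltComplex(sub, agt, "R")


@pytest.fixture
def chiral_pair():
    """Diastereomeric (R, S) complexes against a chiral resolving agent."""
    return make_chiral_complex(ToyChiralSpec(), agent=build_agent(achiral=False),
                               seed=7)


@pytest.fixture
def achiral_pair():
    """Enantiomeric (R, S) complexes: the agent is planar/achiral."""
    return make_chiral_complex(ToyChiralSpec(), agent=build_agent(achiral=True),
                               seed=7)
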