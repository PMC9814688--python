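import numpy as np
import pytest

from cononsol import (LambdaScaling, build_forcefield,
                      default_polymer_species, make_conformers)
from cononsol.synth import make_polymer_chain


@pytest.fixture(scope="session")
def polymer_ff():
    """Unscaled polymer-only force field (plain Lorentz–Berthelot)."""
    return build_forcefield([default_polymer_species()],
                            scaling=LambdaScaling(1.0, 1.0))


@pytest.fixture(scope="session")
def coil32():
    return make_conformers(32, "coil", seed=1)


@pytest.fixture(scope="session")
def globule32():
    return make_conformers(32, "globule", seed=1)


@pytest.fixture()
def chain8(polymer_ff):
    """Small perturbed 8-bead chain for force/energy checks."""
    rng = np.random.default_rng(0)
    st = make_polymer_chain(8)
    st.positions += 0.05 * rng.standard_normal(st.positions.shape)
    return st
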