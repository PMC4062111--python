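import numpy as np
import pytest

from asyndyn import build_canonical_model
from asyndyn.params import PARAMETER_NAMES, InitialConditionSpec, ParameterSet
from asyndyn.simulate import CompiledModel


@pytest.fixture(scope="session")
def model():
    return build_canonical_model()


@pytest.fixture(scope="session")
def compiled(model):
    return CompiledModel(model)


#: A positive placeholder for constants that must not fire in a toy setup.
OFF = 1e-30


def toy_params(**overrides) -> ParameterSet:
    """All 20 constants at a negligible value except the given overrides."""
    vals = {n: OFF for n in PARAMETER_NAMES}
    vals.update(overrides)
    return ParameterSet(values=vals)


@pytest.fixture(scope="session")
def calibrated():
    from asyndyn.fitted import load_calibrated

    return load_calibrated()


@pytest.fixture
def zero_init():
    return InitialConditionSpec(
        monomer_total=0, dimer_total=0, oligomer_total=0, lamp2a=0, proteasome=0, da=0.0
    )
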