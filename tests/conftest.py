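import numpy as np
import pytest

from solvshell.ensemble import build_molecule, cellobiose_template, water_template
from solvshell.generator import GeneratorParams, generate_ensemble


@pytest.fixture(scope="session")
def template():
    return cellobiose_template()


@pytest.fixture()
def beta_fragment(template):
    return build_molecule(template, "beta")


@pytest.fixture(scope="session")
def water_tmpl():
    return water_template()


@pytest.fixture(scope="session")
def tiny_ensemble():
    """3 solutes, 20 waters per solute, 4 configurations: fast shared fixture."""
    params = GeneratorParams(n_solute=3, water_ratio=20, n_configurations=4, seed=42)
    return generate_ensemble(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
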