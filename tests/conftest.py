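import pytest

from priddg import fixtures, structure
from priddg.forcefield import load_default_params
from priddg.minimize import MinimizationSettings
from priddg.model import WildTypeContext

TOY_SEED = 1


@pytest.fixture(scope="session")
def toy_pdb_text():
    return fixtures.make_toy_complex(12, 6, "helix", 4.0, seed=TOY_SEED)


@pytest.fixture(scope="session")
def toy_complex(toy_pdb_text):
    return structure.load_complex(toy_pdb_text)


@pytest.fixture(scope="session")
def separated_complex():
    txt = fixtures.make_toy_complex(12, 6, "helix", 100.0, seed=TOY_SEED)
    return structure.load_complex(txt)


@pytest.fixture(scope="session")
def fast_settings():
    # enough steps to relax toy clashes while keeping the suite quick
    return MinimizationSettings(n_steps=80)


@pytest.fixture(scope="session")
def wt_context(toy_complex, fast_settings):
    return WildTypeContext(toy_complex, fast_settings)


@pytest.fixture(scope="session")
def ff_params():
    return load_default_params()
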