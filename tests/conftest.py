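import numpy as np
import pytest

import twodes as td

# Full-preset datasets and fits are shared session-wide: several test modules
# (and the acceptance tests) interrogate the same pipeline products.


@pytest.fixture(scope="session")
def rt_kinetic_ds():
    return td.generate(td.get_preset("rt_kinetic"))


@pytest.fixture(scope="session")
def k77_kinetic_ds():
    return td.generate(td.get_preset("k77_kinetic"))


@pytest.fixture(scope="session")
def rt_fit(rt_kinetic_ds):
    return td.fit_global(rt_kinetic_ds)


@pytest.fixture(scope="session")
def k77_fit(k77_kinetic_ds):
    return td.fit_global(k77_kinetic_ds)


@pytest.fixture(scope="session")
def rt_lineshape_ds():
    return td.generate(td.get_preset("rt_lineshape"))


@pytest.fixture(scope="session")
def k77_lineshape_ds():
    return td.generate(td.get_preset("k77_lineshape"))


@pytest.fixture(scope="session")
def rt_lineshape_clean():
    return td.generate(td.get_preset("rt_lineshape", sigma_rel=0.0))


@pytest.fixture(scope="session")
def axes_96():
    exc, emi, t = td.make_grid(13_800, 17_600, 96, 1000, 7.5)
    return exc, emi, t


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
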