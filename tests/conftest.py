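"""Shared fixtures: cascade fields, configs, and a rendered trace."""

import numpy as np
import pytest

import mfspec as m

#: config whose box sizes are exact dyadic scales of the cascade fixtures
DYADIC_CFG = m.MfaConfig(dyadic_sizes=True, min_box_px=2)

BINOMIAL_W = (0.25, 0.75)
MULTINOMIAL_W = (0.4, 0.3, 0.2, 0.1)


@pytest.fixture(scope="session")
def binomial_field():
    return m.binomial_measure_1d(m.CascadeSpec(BINOMIAL_W, depth=12))


@pytest.fixture(scope="session")
def multinomial_field():
    return m.multinomial_measure_2d(m.CascadeSpec(MULTINOMIAL_W, depth=9))


@pytest.fixture(scope="session")
def binomial_spectrum(binomial_field):
    return m.analyze(binomial_field, DYADIC_CFG)


@pytest.fixture(scope="session")
def multinomial_spectrum(multinomial_field):
    return m.analyze(multinomial_field, DYADIC_CFG)


@pytest.fixture(scope="session")
def uniform_2d_spectrum():
    return m.analyze(m.MassField(np.ones((256, 256))), DYADIC_CFG)


@pytest.fixture()
def cell_spectrum():
    return m.synth_ftir_spectrum(m.SyntheticCellSpec(seed=11))
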