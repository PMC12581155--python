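import dataclasses

import numpy as np
import pytest

from condensago.contacts import VariantSpec
from condensago.experiments import PRESETS, build_variant_system
from condensago.fixtures import make_hhh_dimer_reference


@pytest.fixture(scope="session")
def hhh_reference():
    return make_hhh_dimer_reference(26)


@pytest.fixture(scope="session")
def tiny_preset():
    return dataclasses.replace(PRESETS["tiny"])


@pytest.fixture(scope="session")
def tiny_system(tiny_preset):
    """A small assembled variant system (strong contacts, with RNA)."""
    system, cset = build_variant_system(
        VariantSpec(4.0, 4.0), tiny_preset, 200.0, seed=11)
    return system, cset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
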