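import random

import pytest

from snoverify.params import Params
from snoverify.motif import scan_cd_layouts
from snoverify.records import SequenceRecord
from snoverify.simulate import SimConfig, make_toy_catalog, make_toy_study


@pytest.fixture
def params():
    return Params()


@pytest.fixture(scope="session")
def toy_cfg():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def toy_study(toy_cfg):
    return make_toy_study(toy_cfg)


@pytest.fixture(scope="session")
def one_family():
    """(profile, target, layout) for a single intact generated gene."""
    cfg = SimConfig(seed=11, n_families=1)
    catalog, targets = make_toy_catalog(cfg, random.Random(11), Params())
    profile = catalog[0]
    layout = scan_cd_layouts(profile.reference_seq, Params())[0]
    return profile, targets[0], layout


def rand_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
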