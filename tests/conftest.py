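import numpy as np
import pytest

from il4model import build_human_panel, build_mouse_panel


@pytest.fixture(scope="session")
def human_panel():
    return build_human_panel()


@pytest.fixture(scope="session")
def mouse_panel():
    return build_mouse_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230406)


def free_pairs_of(config):
    """All (ligand, receptor) pairs with nonzero binding in a panel config."""
    pairs = []
    for lig, aff in config.affinities.items():
        for receptor, ka in (
            ("alpha", aff.ka_alpha),
            ("gamma", aff.ka_gamma),
            ("il13ra1", aff.ka_13),
        ):
            if ka > 0:
                pairs.append((lig, receptor))
    return tuple(pairs)


def true_log10_ka(config, pair):
    lig, receptor = pair
    aff = config.affinities[lig]
    ka = {"alpha": aff.ka_alpha, "gamma": aff.ka_gamma, "il13ra1": aff.ka_13}[receptor]
    return float(np.log10(ka))
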