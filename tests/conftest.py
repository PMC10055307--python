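import math

import numpy as np
import pytest

from coopkin import (
    ConformationalEnsemble,
    DoubleDrugScheme,
    LigandProfile,
    make_preset,
)


@pytest.fixture(scope="session")
def mb1():
    return make_preset("AurA-danusertib-Mb1")


@pytest.fixture(scope="session")
def mb2():
    return make_preset("AurA-danusertib-Mb2")


@pytest.fixture(scope="session")
def mb3():
    return make_preset("AurA-danusertib-Mb3")


@pytest.fixture(scope="session")
def ablkd():
    return make_preset("AblKD-imatinib-asciminib")


@pytest.fixture(scope="session")
def ablfl():
    return make_preset("AblFL-imatinib-asciminib")


@pytest.fixture(scope="session")
def null_preset():
    return make_preset("null")


def random_scheme(rng: np.random.Generator, n_states: int = 2,
                  allow_exclusive: bool = True) -> DoubleDrugScheme:
    """A random but well-posed double-drugging scheme for property tests."""
    states = tuple(f"s{i}" for i in range(n_states))
    weights = (1.0, *np.exp(rng.uniform(-3, 3, n_states - 1)))

    def profile(name, site):
        kd = {}
        while not any(math.isfinite(v) for v in kd.values()):
            for s in states:
                if allow_exclusive and rng.random() < 0.25:
                    kd[s] = math.inf
                else:
                    kd[s] = 10.0 ** rng.uniform(-10, -6)
        return LigandProfile(name=name, site=site, kd_per_state=kd)

    coupling = {s: float(np.exp(rng.uniform(-1, 1))) for s in states}
    return DoubleDrugScheme(
        ensemble=ConformationalEnsemble(states, weights),
        ortho=profile("O", "orthosteric"),
        allo=profile("A", "allosteric"),
        catalytic_weight_per_state={states[0]: 1.0},
        coupling_per_state=coupling,
    )
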