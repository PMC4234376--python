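import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oligoms import ModificationAlphabet, MotifPlant, PlantedMod, SimScenario

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def alphabet():
    return ModificationAlphabet.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_scenario():
    """A fast two-condition study on a 320-nt parent: one acetyl on a
    3-copy CCG product (window-disambiguable) and one on a unique
    UUUCCG product."""
    occ = (("WT", 1.0), ("mutant", 0.0))
    return SimScenario(
        parent_length=320,
        gc_content=0.5,
        motif_plants=(
            MotifPlant("CCG", 3, (40, 150, 260)),
            MotifPlant("UUUCCG", 1, (200,)),
        ),
        planted_mods=(
            PlantedMod(151, "ac4C", occ),
            PlantedMod(204, "ac4C", occ),
        ),
        windows=((100, 180),),
        seed=11,
        parent_id="small-synthetic",
    )
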