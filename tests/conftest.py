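import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lepilink import popsim

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def f2301():
    """The female-informative backcross family emulating F2301 (seed 7)."""
    markers, trait, rmap = popsim.f2301_panel()
    family = popsim.simulate_family(
        popsim.f2301_design(seed=7), markers, trait, rmap
    )
    return family, markers, trait


@pytest.fixture(scope="session")
def mapping_family():
    """A male-informative backcross with the chromosome-walk marker panel."""
    markers, trait, rmap = popsim.mapping_panel()
    family = popsim.simulate_family(
        popsim.mapping_design(seed=11, n_survivors=500, n_control=50),
        markers, trait, rmap,
    )
    return family, markers, trait, rmap


def simulate_null_family(seed: int):
    """A family whose trait is unlinked to every marker (null association)."""
    markers = [
        popsim.MarkerDef(
            f"M{g:02d}", g, 10, popsim.DOMINANT,
            1 if g % 2 else 0, 0 if g % 2 else 1,
        )
        for g in range(1, 32)
    ]
    trait = popsim.TraitLocus(group=32, position=5)
    layouts = popsim.build_layouts(markers, trait)
    rmap = popsim.RecombMap.uniform(layouts, 0.1)
    design = popsim.FamilyDesign(
        name="null", informative_sex="female", cross="backcross",
        n_survivor_target=29, n_control=30, seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return popsim.simulate_family(design, markers, trait, rmap)
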