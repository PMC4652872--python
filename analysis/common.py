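"""Shared constants and helpers for the numbered analysis drivers.

Every driver is deterministic (fixed seeds) and writes its tables under
``results/`` at the repository root; drivers regenerate any upstream
artifact they need, so each can be run on its own.
"""

from pathlib import Path

from lepilink import popsim

RESULTS = Path(__file__).resolve().parent.parent / "results"

F2301_SEED = 7
MAPPING_SEEDS = {"G2016": 11, "G2020": 12, "G2029": 13}
# selected (rr) progeny per mapping family; totals the study's 72
MAPPING_SIZES = {"G2016": 20, "G2020": 26, "G2029": 26}


def f2301_family():
    """The female-informative backcross (161 AFLPs / 31 groups / 59 progeny)."""
    markers, trait, rmap = popsim.f2301_panel()
    family = popsim.simulate_family(
        popsim.f2301_design(seed=F2301_SEED), markers, trait, rmap
    )
    return family, markers, trait


def mapping_families():
    """One male-informative backcross and two F2 families (72 rr progeny)."""
    markers, trait, rmap = popsim.mapping_panel()
    families = {}
    for name, seed in MAPPING_SEEDS.items():
        cross = "backcross" if name == "G2016" else "F2"
        design = popsim.mapping_design(
            seed=seed,
            n_survivors=MAPPING_SIZES[name],
            n_control=20 if name == "G2016" else 0,
            cross=cross,
            name=name,
        )
        families[name] = popsim.simulate_family(design, markers, trait, rmap)
    return families, markers, trait, rmap


def ensure_results() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
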