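"""Shared fixtures: a small synthetic scenario and scoring scheme.

The small scenario (20 background / 3 CBR / 2 paralog families, 8 species)
keeps per-test screen runs to a few seconds; the full default scenario is
exercised only by the end-to-end acceptance test.
"""

from __future__ import annotations

import pytest

from regenscreen.screen import ScreenConfig
from regenscreen.similarity import ScoringScheme
from regenscreen.synthetic import SpeciesSpec, simulate_species_set

SMALL_SEED = 7


def small_specs(n_background: int = 20) -> list[SpeciesSpec]:
    specs = []
    for prefix, cls, n in (("wbr", "WBR", 3), ("hra", "HRA", 2),
                           ("lra", "LRA", 2), ("cfm", "CONFIRM", 1)):
        specs += [SpeciesSpec(f"{prefix}{i + 1}", cls, n_background, 0.05)
                  for i in range(n)]
    return specs


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_scenario():
    """(proteomes, truth) for a fast 8-species scenario, seed 7."""
    return simulate_species_set(small_specs(), n_cbr=3, n_paralog=2, seed=SMALL_SEED)


@pytest.fixture(scope="session")
def small_config() -> ScreenConfig:
    return ScreenConfig(
        wbr=("wbr1", "wbr2", "wbr3"),
        hra=("hra1", "hra2"),
        lra=("lra1", "lra2"),
        confirm=("cfm1",),
    )
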