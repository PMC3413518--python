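"""Shared fixtures: seeded synthetic families and the stand-in PSY3 trio."""

import pytest

from grasstruct import synthio
from grasstruct.synthetic_psy3 import build_synthetic_psy3

GRASS_TREE = "(rice,((maize,sorghum),(brachypodium,wheat)));"
GRASS_TAXA = ("rice", "maize", "sorghum", "brachypodium", "wheat")

#: forced losses reproducing the grass PSY3 scenario: third ancestral intron
#: lost independently in sorghum and on the Brachypodium+wheat stem, first
#: intron lost in wheat only.
PSY3_SCENARIO = (
    (3, "sorghum", "simple_deletion"),
    (3, "brachypodium+wheat", "simple_deletion"),
    (1, "wheat", "repeat_mediated"),
)


@pytest.fixture(scope="session")
def grass_family():
    """Zero-noise five-taxon family with the PSY3-like loss scenario."""
    cfg = synthio.FamilyConfig(
        taxa=GRASS_TAXA,
        tree=GRASS_TREE,
        forced_losses=PSY3_SCENARIO,
        loss_prob_per_branch=0.0,
        seed=42,
    )
    return synthio.simulate_gene_family(cfg)


@pytest.fixture(scope="session")
def psy3():
    return build_synthetic_psy3(seed=1)
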