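"""Shared fixtures: small synthetic references and studies."""

import numpy as np
import pytest

from twobradm import BCGI
from twobradm.simulate import build_synthetic_reference, default_design, make_case_control

BASES = "ACGT"


def random_background(rng: np.random.Generator, length: int) -> str:
    """Uniform random sequence; may contain incidental recognition sites."""
    return "".join(rng.choice(list(BASES), size=length))


def plant_site(background: str, pos: int, spacer: str = "AACCGG",
               enzyme=BCGI) -> str:
    """Overwrite background with a CGA<spacer>TGC recognition site at pos."""
    site = "CGA" + spacer + "TGC"
    assert len(site) == enzyme.pattern_length
    return background[:pos] + site + background[pos + len(site):]


@pytest.fixture(scope="session")
def five_species_reference():
    """10 genomes / 5 species (2 genomes each) with 25 tags per genome."""
    species = [f"Species_{c}" for c in "ABCDE"]
    genomes, taxonomy, tags_by_genome, db = build_synthetic_reference(
        species, tags_per_genome=25, genomes_per_species=2, seed=11)
    return species, genomes, taxonomy, tags_by_genome, db


@pytest.fixture(scope="session")
def default_study():
    """Default 26-vs-18 case-control study (fixed seed)."""
    return make_case_control(default_design(seed=101))
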