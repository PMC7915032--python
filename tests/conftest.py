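import numpy as np
import pytest

from lcrevol.seqio import (
    AlignedMember,
    OrthologGroup,
    Sequence,
    SpeciesPanel,
    species_tag,
)

PANEL = SpeciesPanel()
SP = list(PANEL)


def make_group(group_id, aligned_by_species, panel=PANEL):
    """Build an OrthologGroup from {species: aligned string}."""
    members = [
        AlignedMember(f"{group_id}_{species_tag(s)}", s, a)
        for s, a in aligned_by_species.items()
    ]
    return OrthologGroup(group_id, members, panel=panel)


@pytest.fixture
def panel():
    return PANEL


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), size=n)])
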