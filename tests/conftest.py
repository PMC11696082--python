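"""Shared fixtures: small panels, taxonomies and read builders.

Everything is generated programmatically and seeded; no fixture files.
"""

import numpy as np
import pytest

from sedascope import Read, build_panel
from sedascope.taxassign import Taxonomy


@pytest.fixture(scope="session")
def small_panel():
    """8 species / 4 genera / 2 families, 300-nt circular references."""
    taxonomy, entries = build_panel(
        n_families=2, genera_per_family=2, species_per_genus=2,
        ref_length=300, divergence=0.1, seed=5,
    )
    return taxonomy, entries


@pytest.fixture(scope="session")
def small_taxonomy(small_panel):
    return Taxonomy(small_panel[0].nodes)


def make_read(seq, rid="r", qual_char="I"):
    return Read(id=rid, seq=seq, qual=qual_char * len(seq))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
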