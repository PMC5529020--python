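"""Shared fixtures: tiny toxin sets, layouts and simulated recordings."""

from __future__ import annotations

import numpy as np
import pytest

from epimap import (
    ToxinRecord,
    assign_layout,
    build_library,
)
from epimap.simulate import NoiseModel, simulate_intensities, simulate_toxin_set


def make_toxin(accession: str, sequence: str, family: str = "FAM",
               species: str = "Sp x") -> ToxinRecord:
    return ToxinRecord(
        accession=accession, species=species, family=family, sequence=sequence
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_array():
    """A small planted-epitope array: toxins, truth, layout, both recordings."""
    toxins, truth = simulate_toxin_set(
        n_toxins=24,
        length_range=(40, 60),
        n_epitopes=1,
        effect_size=2000.0,
        seed=11,
        carrier_fraction=0.8,
    )
    library = build_library(toxins)
    layout = assign_layout(library, replicates=5, corner_field_count=200, seed=12)
    background, antivenom = simulate_intensities(layout, truth, NoiseModel(seed=13))
    return {
        "toxins": toxins,
        "truth": truth,
        "library": library,
        "layout": layout,
        "background": background,
        "antivenom": antivenom,
    }
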