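import numpy as np
import pandas as pd
import pytest

from humgut import FeatureTable, SampleMetadata, TaxonomyMap


@pytest.fixture
def toy_table():
    """6 samples x 5 ASVs with hand-checkable presence patterns."""
    #            a1 a2 a3 a4 a5
    counts = [
        [3, 0, 1, 0, 0],  # Fam wild 1
        [2, 0, 0, 0, 0],  # Fam wild 2
        [3, 5, 1, 0, 0],  # Fam captive 1
        [0, 2, 0, 0, 0],  # Fam captive 2
        [0, 4, 0, 7, 0],  # human 1
        [0, 1, 0, 2, 0],  # human 2
    ]
    return FeatureTable(
        ["w1", "w2", "c1", "c2", "h1", "h2"],
        ["a1", "a2", "a3", "a4", "a5"],
        counts,
    )


@pytest.fixture
def toy_meta():
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["w1", "w2", "c1", "c2", "h1", "h2"],
                "family": ["Bovidae"] * 4 + ["Hominidae"] * 2,
                "status": ["wild", "wild", "captive", "captive", "human", "human"],
                "population": ["", "", "", "", "Malawi", "Venezuela"],
            }
        )
    )


@pytest.fixture
def toy_taxonomy():
    return TaxonomyMap(
        {
            "a1": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                   "Clostridiaceae", "Clostridium sensu stricto 1"),
            "a2": ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
                   "Bacteroidaceae", "Bacteroides"),
            "a3": ("Archaea", "Methanobacteriota", "Methanobacteria",
                   "Methanobacteriales", "Methanobacteriaceae", "Methanobrevibacter"),
            "a4": ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
                   "Prevotellaceae", "Prevotella"),
            "a5": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                   "Clostridiaceae", "Clostridium sensu stricto 13"),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
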