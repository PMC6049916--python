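import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from blendr.celltype_db import MarkerDatabase, MarkerEntry
from blendr.core import ExpressionMatrix
from blendr.simulate import make_profiles, make_synthetic_db


@pytest.fixture
def toy_db() -> MarkerDatabase:
    """Three claims, two genes, no cross-category overlap."""
    return MarkerDatabase.from_entries(
        [
            MarkerEntry("GFAP", "Astrocyte", "pubA"),
            MarkerEntry("SNAP25", "Neuron_All", "pubB"),
            MarkerEntry("GFAP", "Astrocyte", "pubC"),
        ]
    )


@pytest.fixture(scope="session")
def profiles10():
    """Ten-type profile set shared by the simulator-driven tests."""
    return make_profiles(n_genes=120, markers_per_type=8, n_types=10, seed=11)


@pytest.fixture(scope="session")
def db10(profiles10):
    return make_synthetic_db(profiles10, pubs_per_type=2, seed=11)


def random_expression(
    rng: np.random.Generator, n_probes: int, n_samples: int, probes_per_gene: int = 2
) -> ExpressionMatrix:
    """Random annotated matrix with several probes per gene."""
    values = pd.DataFrame(
        rng.normal(8.0, 2.0, size=(n_probes, n_samples)),
        index=[f"probe{i}" for i in range(n_probes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    symbols = pd.Series(
        [f"GENE{i // probes_per_gene}" for i in range(n_probes)], index=values.index
    )
    return ExpressionMatrix(values=values, gene_symbols=symbols)
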