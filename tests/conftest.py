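import numpy as np
import pandas as pd
import pytest

from protdesign_eval import (
    IndicatorTable,
    load_benchmark_config,
    load_denovo_table,
    load_singlechain_table,
)
from protdesign_eval.baselines import ideal_helix_coords
from protdesign_eval.io import Residue, StructureModel


@pytest.fixture(scope="session")
def benchmark_config():
    return load_benchmark_config()


@pytest.fixture(scope="session")
def denovo_table():
    return load_denovo_table()


@pytest.fixture(scope="session")
def singlechain_table():
    return load_singlechain_table()


@pytest.fixture
def toy_table():
    """Small three-method table exercising every orientation tag."""
    df = pd.DataFrame(
        {
            "Recovery": [0.5, 0.4, 0.1],
            "Time (s)": [10.0, 100.0, 50.0],
            "RMSD (Å)": [1.0, 2.0, 8.0],
        },
        index=["good", "mid", "bad"],
    )
    return IndicatorTable(
        data=df,
        orientation={
            "Recovery": "benefit",
            "Time (s)": "cost-linear",
            "RMSD (Å)": "cost-reciprocal",
        },
    )


def structure_from_coords(coords, sequence=None, name="model"):
    coords = np.asarray(coords, dtype=float)
    sequence = sequence or "A" * len(coords)
    residues = [
        Residue(number=i + 1, code=aa, ca=coords[i])
        for i, aa in enumerate(sequence)
    ]
    return StructureModel(id=name, residues=residues)


@pytest.fixture
def helix_model():
    """Ideal 20-residue α-helix (rise 1.5 Å, 100° twist)."""
    return structure_from_coords(ideal_helix_coords(20), name="helix")


@pytest.fixture
def rng():
    return np.random.default_rng(20240123)
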