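import numpy as np
import pytest

from glomquant.synthetic import (
    AtlasSpec,
    CellTypeSpec,
    EllipsoidSpec,
    ExpressionSimSpec,
    PlantedPair,
    SimTruth,
    default_atlas_spec,
)


@pytest.fixture
def small_spec():
    """Compact two-glomerulus atlas for fast unit tests."""
    return AtlasSpec(
        stack_shape=(16, 48, 48),
        glomeruli=(
            EllipsoidSpec("VA1d", (8, 14, 24), (4, 7, 7)),
            EllipsoidSpec("VA1v", (8, 32, 24), (4, 7, 7)),
        ),
    )


@pytest.fixture
def medium_spec():
    return default_atlas_spec((24, 72, 72))


@pytest.fixture
def noiseless_truth():
    return SimTruth(
        seed=7,
        mistarget_fraction={"VA1v": 0.2},
        protein_mean={"VA1d": 150.0, "VA1v": 50.0},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_expression_spec(n_decoys=20, effect=3.0, dispersion=2.0, n_pairs=1):
    """Expression sim spec with VA1d/VA1v ORN and PN types and planted pairs."""
    types = (
        CellTypeSpec("VA1d-ORN", "ORN", "VA1d"),
        CellTypeSpec("VA1v-ORN", "ORN", "VA1v"),
        CellTypeSpec("VA1d-PN", "PN", "VA1d"),
        CellTypeSpec("VA1v-PN", "PN", "VA1v"),
    )
    pairs = tuple(
        PlantedPair(
            ligand=f"lig{i}",
            receptor=f"rec{i}",
            sender_hi="VA1v-ORN",
            sender_lo="VA1d-ORN",
            receiver_hi="VA1d-PN",
            receiver_lo="VA1v-PN",
            log2_effect=effect,
        )
        for i in range(n_pairs)
    )
    return ExpressionSimSpec(
        n_genes=n_decoys,
        cell_types=types,
        planted_pairs=pairs,
        nb_dispersion=dispersion,
    )
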