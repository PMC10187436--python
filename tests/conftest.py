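import numpy as np
import pytest

from plcdmix.energy_model import InteractionModel
from plcdmix.lattice_engine import Frame
from plcdmix.sequence_model import PolymerSpecies


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ab_model():
    """Two generic bead types, all contacts -1, no electrostatics."""
    return InteractionModel(
        bead_types=("A", "B"),
        contact_energy=np.array([[-1.0, -1.0], [-1.0, -1.0]]),
    )


@pytest.fixture
def ab_sequences():
    return {"A": ("A",) * 4, "B": ("B",) * 4}


def make_frame(box, chains, sequences):
    """Helper: build a Frame from plain coordinate lists."""
    return Frame(
        box=tuple(box),
        chains=[(label, np.array(coords, dtype=np.int64)) for label, coords in chains],
        sequences=sequences,
    )


@pytest.fixture
def two_chain_frame(ab_sequences):
    """Two 4-bead chains in face contact, far from the box seam."""
    return make_frame(
        (12, 12, 12),
        [
            ("A", [(3, 3, 3), (4, 3, 3), (5, 3, 3), (6, 3, 3)]),
            ("B", [(3, 4, 3), (4, 4, 3), (5, 4, 3), (6, 4, 3)]),
        ],
        ab_sequences,
    )
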