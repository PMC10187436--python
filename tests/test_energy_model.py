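import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plcdmix.energy_model import (
    InteractionModel,
    UnknownBeadTypeError,
    build_scenario_matrix,
    default_plcd_model,
    pair_energy,
    read_contact_table,
    system_energy,
    write_contact_table,
)
from tests.conftest import make_frame


def test_pair_energy_coupling_off(ab_model):
    assert pair_energy("A", "B", 0.3, -0.7, ab_model) == pytest.approx(-1.0)


def test_pair_energy_complementary_charges_cancel():
    m = InteractionModel(("A", "B"), np.array([[-2.0, -1.5], [-1.5, -2.0]]), w_el=3.0)
    # opposite chain charges average to zero: base energy exactly
    assert pair_energy("A", "B", 0.4, -0.4, m) == pytest.approx(-1.5)


def test_pair_energy_quadratic_penalty():
    m = InteractionModel(("A",), np.array([[-2.0]]), w_el=1.0)
    assert pair_energy("A", "A", 0.1, 0.1, m) == pytest.approx(-1.99)


def test_pair_energy_like_charges_weaken_attraction():
    """Replacing a +/- chain pair by a like-signed pair raises the energy."""
    m = InteractionModel(("A",), np.array([[-1.0]]), w_el=2.0)
    mixed = pair_energy("A", "A", 0.3, -0.3, m)
    same = pair_energy("A", "A", 0.3, 0.3, m)
    assert same > mixed


@given(
    st.floats(-1, 1), st.floats(-1, 1),
    st.sampled_from(["A", "B"]), st.sampled_from(["A", "B"]),
)
@settings(deadline=None, max_examples=40)
def test_pair_energy_exchange_symmetry(na, nb, ti, tj):
    m = InteractionModel(("A", "B"), np.array([[-1.0, -0.5], [-0.5, -2.0]]), w_el=1.3)
    assert pair_energy(ti, tj, na, nb, m) == pytest.approx(
        pair_energy(tj, ti, nb, na, m)
    )


def test_pair_energy_unknown_type(ab_model):
    with pytest.raises(UnknownBeadTypeError):
        pair_energy("A", "Z", 0, 0, ab_model)


@pytest.mark.parametrize(
    "scenario,expected",
    [
        ("equal", [[-1.0, -1.0], [-1.0, -1.0]]),
        ("hetero_stronger", [[-1.0, -1.5], [-1.5, -1.0]]),
        ("homo_stronger", [[-1.5, -1.0], [-1.0, -1.5]]),
        ("asymmetric_A_weak", [[-0.5, -1.0], [-1.0, -1.0]]),
    ],
)
def test_scenario_matrices(scenario, expected):
    m = build_scenario_matrix(scenario, -1.0, 0.5)
    assert np.allclose(m.contact_energy, expected)


def test_scenario_matrix_rejects_bad_inputs():
    with pytest.raises(ValueError):
        build_scenario_matrix("equal", -1.0, -0.1)
    with pytest.raises(ValueError):
        build_scenario_matrix("equal", 0.5, 0.1)
    with pytest.raises(ValueError):
        build_scenario_matrix("bogus", -1.0, 0.1)


def test_interaction_model_requires_symmetry():
    with pytest.raises(ValueError):
        InteractionModel(("A", "B"), np.array([[-1.0, -0.5], [-0.4, -1.0]]))


def test_system_energy_no_contacts(ab_model, ab_sequences):
    frame = make_frame(
        (20, 20, 20),
        [("A", [(0, 0, 0), (1, 0, 0)]), ("B", [(10, 10, 10), (11, 10, 10)])],
        {"A": ("A",) * 2, "B": ("B",) * 2},
    )
    assert system_energy(frame, {"A": 0.0, "B": 0.0}, ab_model) == 0.0


def test_system_energy_hand_counted_pair_grid(ab_model):
    """Two parallel 2-bead chains one site apart: enumerate the 2x2 bead
    pairs by hand.  Every inter-chain pair is within the 26-shell (Chebyshev
    distance 1), and each intra-chain pair is a bond, so E = 4 x (-1)."""
    frame = make_frame(
        (12, 12, 12),
        [("A", [(3, 3, 3), (4, 3, 3)]), ("B", [(3, 4, 3), (4, 4, 3)])],
        {"A": ("A",) * 2, "B": ("B",) * 2},
    )
    e = system_energy(frame, {"A": 0.0, "B": 0.0}, ab_model)
    assert e == pytest.approx(-4.0)


def test_system_energy_linearity(two_chain_frame, ab_model):
    e1 = system_energy(two_chain_frame, {"A": 0.0, "B": 0.0}, ab_model)
    doubled = InteractionModel(
        ab_model.bead_types, 2.0 * ab_model.contact_energy, w_el=0.0
    )
    e2 = system_energy(two_chain_frame, {"A": 0.0, "B": 0.0}, doubled)
    assert e2 == pytest.approx(2.0 * e1)
    assert e1 < 0


def test_system_energy_rejects_overlap(ab_model, ab_sequences):
    frame = make_frame(
        (10, 10, 10),
        [("A", [(0, 0, 0), (1, 0, 0)]), ("B", [(0, 0, 0), (0, 1, 0)])],
        {"A": ("A",) * 2, "B": ("B",) * 2},
    )
    with pytest.raises(ValueError, match="overlap"):
        system_energy(frame, {"A": 0.0, "B": 0.0}, ab_model)


def test_contact_table_roundtrip(tmp_path):
    m = default_plcd_model(w_el=0.7)
    path = tmp_path / "matrix.tsv"
    write_contact_table(m, path)
    m2 = read_contact_table(path, w_el=0.7)
    assert m2.bead_types == m.bead_types
    assert np.allclose(m2.contact_energy, m.contact_energy)


def test_default_plcd_matrix_sticker_hierarchy():
    m = default_plcd_model()
    e = m.contact_energy
    i = {t: k for k, t in enumerate(m.bead_types)}
    assert e[i["Y"], i["F"]] < e[i["Y"], i["R"]] < e[i["G"], i["S"]] < 0
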