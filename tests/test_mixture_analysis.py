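import numpy as np
import pytest

from plcdmix.energy_model import shell_offsets
from plcdmix.mixture_analysis import (
    additivity_null,
    chain_rg,
    classify_cooperativity,
    crosslink_parameter,
    match_csat,
    rg_profile,
    tie_line,
)
from tests.conftest import make_frame


# ---------------------------------------------------------------------------
# Additivity null and cooperativity
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,expected", [(1.0, 2.0), (0.0, 4.0), (0.5, 3.0)]
)
def test_additivity_null(a, expected):
    assert additivity_null(2.0, 4.0, a) == pytest.approx(expected)


def test_additivity_null_rejects_bad_fraction():
    with pytest.raises(ValueError):
        additivity_null(1.0, 1.0, 1.2)


def test_classify_cooperativity_three_regimes():
    on_line = [(0.25, 3.5, 0.05), (0.5, 3.0, 0.05), (0.75, 2.5, 0.05)]
    below = [(a, c - 0.5, se) for a, c, se in on_line]
    above = [(a, c + 0.5, se) for a, c, se in on_line]
    assert classify_cooperativity(on_line, 2.0, 4.0).classification == "additive"
    res = classify_cooperativity(below, 2.0, 4.0)
    assert res.classification == "positive" and res.mean_deviation < 0
    res = classify_cooperativity(above, 2.0, 4.0)
    assert res.classification == "negative" and res.mean_deviation > 0


def test_classify_cooperativity_requires_interior_points():
    with pytest.raises(ValueError):
        classify_cooperativity([(1.0, 2.0, 0.1)], 2.0, 4.0)
    with pytest.raises(ValueError):
        classify_cooperativity([], 2.0, 4.0)


# ---------------------------------------------------------------------------
# Tie lines
# ---------------------------------------------------------------------------


def test_tie_line_diagonal_is_heterotypic():
    tl = tie_line((1, 1), (2, 2), (5, 5), se_dilute=(0.05, 0.05), se_dense=(0.1, 0.1))
    assert tl.slope_dilute_to_total == pytest.approx(1.0)
    assert tl.slope_total_to_dense == pytest.approx(1.0)
    assert tl.classification == "heterotypic_dominant"
    assert tl.collinearity_gap == pytest.approx(0.0)


def test_tie_line_steep_slope_attributes_to_B():
    tl = tie_line((1, 2), (2, 4), (4, 8), se_dilute=(0.01, 0.01), se_dense=(0.01, 0.01))
    assert tl.slope_dilute_to_total == pytest.approx(2.0)
    assert tl.slope_total_to_dense == pytest.approx(2.0)
    assert tl.classification == "homotypic_B_dominant"


def test_tie_line_shallow_slope_attributes_to_A():
    tl = tie_line((2, 1), (4, 2), (8, 4), se_dilute=(0.01, 0.01), se_dense=(0.01, 0.01))
    assert tl.classification == "homotypic_A_dominant"


def test_tie_line_vertical_segment_flagged():
    tl = tie_line((1, 1), (1, 5), (1, 9))
    assert tl.vertical and np.isinf(tl.slope_dilute_to_total)


# ---------------------------------------------------------------------------
# Crosslinking parameter
# ---------------------------------------------------------------------------


def _hand_frame():
    """Two A-chains and one B-chain with exhaustively countable contacts.

    Chains are parallel 2-bead rods one lattice unit apart:
        A0 at y=3, A1 at y=4, B0 at y=5  (all x in {3,4}, z=3)
    Every inter-chain bead pair between adjacent rods is a 26-shell contact
    (Chebyshev distance 1); between A0 and B0 the distance is 2 -> none.
    """
    seqs = {"A": ("A",) * 2, "B": ("B",) * 2}
    return make_frame(
        (12, 12, 12),
        [
            ("A", [(3, 3, 3), (4, 3, 3)]),
            ("A", [(3, 4, 3), (4, 4, 3)]),
            ("B", [(3, 5, 3), (4, 5, 3)]),
        ],
        seqs,
    )


def test_crosslink_parameter_hand_count():
    """Direct arithmetic from the operational definition.

    Contacts: A0-A1: 4 bead pairs; A1-B0: 4; A0-B0: 0.
    Observed per chain (contacts to A, contacts to B):
        A0: (4, 0); A1: (4, 4); B0: (0, 4).
    Expectations with B_A = 4, B_B = 2, B_tot = 6, b_c = 2:
        for A-chains: p(A) = (4-2)/4 = 1/2, p(B) = 2/4 = 1/2
        for B-chain:  p(A) = 4/4 = 1,     p(B) = (2-2)/4 = 0.
    L_AA = (4+4)/(4*0.5 + 8*0.5) = 8/6; L_AB = 4/6; L_BA = 4/4 = 1.
    """
    frame = _hand_frame()
    L, defined = crosslink_parameter([frame], ["A", "B"])
    assert L[0, 0] == pytest.approx(8 / 6)
    assert L[0, 1] == pytest.approx(4 / 6)
    assert L[1, 0] == pytest.approx(1.0)
    assert defined[0, 0] and defined[0, 1] and defined[1, 0]
    # no B-B inter-chain expectation exists with a single B chain
    assert not defined[1, 1]


def test_crosslink_random_relabeling_gives_unity(rng):
    """One species randomly relabeled as two: L = 1 within noise.

    Build a dense random cluster of 2-bead chains, then relabel half of
    them as species B.  The expectation correction makes the statistic
    exactly 1 on average; a single frame realization should be close.
    """
    chains = []
    for x in range(2, 7):
        for y in range(2, 7):
            for z in range(2, 7, 2):
                chains.append([(x, y, z), (x, y, z + 1)])
    # average the statistic over several random label assignments
    Ls = []
    for _ in range(20):
        labels = np.array(["A"] * 25 + ["B"] * 25)
        rng.shuffle(labels)
        frame = make_frame(
            (12, 12, 12),
            list(zip(labels, chains)),
            {"A": ("A",) * 2, "B": ("B",) * 2},
        )
        L, defined = crosslink_parameter([frame], ["A", "B"])
        assert defined.all()
        Ls.append(L)
    assert np.allclose(np.mean(Ls, axis=0), 1.0, atol=0.05)


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------


def test_chain_rg_straight_rod():
    """Collinear equally spaced 4-bead chain: Rg^2 = (1/4) sum (i - 1.5)^2
    = (2.25 + 0.25 + 0.25 + 2.25)/4 = 5/4."""
    coords = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]
    assert chain_rg(coords, (20, 20, 20)) == pytest.approx(np.sqrt(5 / 4))


def test_chain_rg_plaquette():
    """Four beads on a unit square: every bead is at distance sqrt(2)/2 from
    the center, so Rg = sqrt(1/2)."""
    coords = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
    assert chain_rg(coords, (20, 20, 20)) == pytest.approx(np.sqrt(0.5))


def test_chain_rg_unwraps_across_seam():
    """A rod straddling the periodic seam must not be torn apart."""
    coords = [(9, 0, 0), (0, 0, 0), (1, 0, 0), (2, 0, 0)]
    assert chain_rg(coords, (10, 10, 10)) == pytest.approx(np.sqrt(5 / 4))


# ---------------------------------------------------------------------------
# Matched-c_sat bisection
# ---------------------------------------------------------------------------


def test_match_csat_on_analytic_function():
    # a monotone stand-in for c_sat(scale): attraction up, c_sat down
    csat = lambda s: 0.01 * np.exp(-3.0 * (s - 1.0))
    scale, val = match_csat(csat, target=0.005, lo=0.5, hi=2.0, rel_tol=0.01)
    assert val == pytest.approx(0.005, rel=0.02)
    assert scale == pytest.approx(1.0 + np.log(2) / 3.0, abs=0.05)


def test_match_csat_requires_bracketing():
    with pytest.raises(ValueError):
        match_csat(lambda s: 1.0, target=2.0, lo=0.1, hi=1.0)
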