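import itertools

import numpy as np
import pytest

from plcdmix.phase_profiler import (
    LogisticFit,
    RadialProfile,
    SinglePhaseError,
    chain_adjacency,
    coexisting_concentrations,
    condensate_com,
    fit_logistic,
    largest_cluster,
    radial_density,
    two_component_diagram,
)
from tests.conftest import make_frame

SEQS = {"A": ("A",) * 2, "B": ("B",) * 2}


def _pair(p0, p1):
    return [tuple(p0), tuple(p1)]


def test_largest_cluster_dispersed_frame_is_flagged():
    frame = make_frame(
        (20, 20, 20),
        [
            ("A", _pair((0, 0, 0), (1, 0, 0))),
            ("A", _pair((8, 8, 8), (9, 8, 8))),
            ("A", _pair((15, 15, 15), (16, 15, 15))),
        ],
        SEQS,
    )
    members, dispersed = largest_cluster(frame)
    assert dispersed and len(members) == 1


def test_largest_cluster_pair_plus_distant_chain():
    frame = make_frame(
        (20, 20, 20),
        [
            ("A", _pair((3, 3, 3), (4, 3, 3))),
            ("B", _pair((3, 4, 3), (4, 4, 3))),
            ("A", _pair((15, 15, 15), (16, 15, 15))),
        ],
        SEQS,
    )
    members, dispersed = largest_cluster(frame)
    assert not dispersed and sorted(members) == [0, 1]


def test_largest_cluster_matches_brute_force_closure(rng):
    """Five random chains: compare against a brute-force transitive closure
    over the pairwise chain-contact relation."""
    for trial in range(5):
        chains = []
        for c in range(5):
            start = rng.integers(0, 12, size=3)
            step = rng.integers(-1, 2, size=3)
            if not step.any():
                step = np.array([1, 0, 0])
            chains.append(("A", [tuple(start), tuple((start + step) % 12)]))
        frame = make_frame((12, 12, 12), chains, SEQS)
        adj = chain_adjacency(frame)
        # brute-force: repeated squaring of the adjacency relation
        reach = adj | np.eye(5, dtype=bool)
        for _ in range(5):
            reach = reach @ reach
        comps = {}
        for i in range(5):
            comps.setdefault(frozenset(np.flatnonzero(reach[i])), set()).add(i)
        max_size = max(len(v) for v in comps.values())
        maximal = [sorted(v) for v in comps.values() if len(v) == max_size]
        members, dispersed = largest_cluster(frame)
        if not dispersed:
            assert sorted(members) in maximal


def test_condensate_com_single_site():
    frame = make_frame((10, 10, 10), [("A", _pair((4, 5, 6), (4, 5, 7)))], SEQS)
    com = condensate_com(frame, [0])
    assert np.allclose(com, [4.0, 5.0, 6.5])


def test_condensate_com_straddles_seam():
    """A cluster symmetric about the periodic seam must have its center at
    the seam, not at the box middle."""
    frame = make_frame(
        (10, 10, 10),
        [("A", _pair((9, 0, 0), (0, 0, 0)))],
        SEQS,
    )
    com = condensate_com(frame, [0])
    assert min(abs(com[0] - 9.5), abs(com[0] - (-0.5) % 10)) < 1e-9


def test_condensate_com_matches_naive_mean_away_from_seam(rng):
    """Compact seam-free cluster: the circular mean agrees with the naive
    mean to within the O((spread/box)^2) bias of the circular construction."""
    chains = []
    for i in range(3):
        p = rng.integers(12, 17, size=3)
        chains.append(("A", [tuple(p), tuple(p + (1, 0, 0))]))
    frame = make_frame((30, 30, 30), chains, SEQS)
    com = condensate_com(frame, [0, 1, 2])
    naive = np.vstack([c[1] for c in frame.chains]).mean(axis=0)
    assert np.allclose(com, naive, atol=0.1)


def test_radial_density_concentrated_at_center():
    frame = make_frame(
        (16, 16, 16),
        [("A", _pair((8, 8, 8), (8, 8, 9)))],
        SEQS,
    )
    prof = radial_density([frame])
    assert prof.density["A"][0] > 0
    assert prof.density["A"][3:].sum() == 0


def test_radial_density_identical_coordinates_identical_profiles():
    coords = [(8, 8, 8), (8, 8, 9), (8, 9, 9)]
    f1 = make_frame((16, 16, 16), [("A", coords)], {"A": ("A",) * 3})
    f2 = make_frame((16, 16, 16), [("B", coords)], {"B": ("B",) * 3})
    p1 = radial_density([f1])
    p2 = radial_density([f2])
    assert np.allclose(p1.density["A"], p2.density["B"])


def test_radial_density_uniform_occupancy_is_flat(rng):
    """Random uniform occupancy gives a flat profile at the bulk fraction.

    Averaged over several frames and excluding the innermost bins (whose
    few sites sit at the arbitrarily chosen cluster center and are both
    noisy and selection-biased), every shell should sit near the mean
    occupancy.
    """
    L = 20
    n = 400  # first-bead count; second beads may overlap existing ones
    profs = []
    for _ in range(10):
        sites = rng.choice(L**3, size=n, replace=False)
        xyz = np.column_stack(np.unravel_index(sites, (L, L, L)))
        chains = []
        for p in xyz:
            q = (p + np.array([1, 0, 0])) % L
            chains.append(("A", [tuple(p), tuple(q)]))
        frame = make_frame((L, L, L), chains, SEQS)
        profs.append(radial_density([frame]).density["A"])
    mean_prof = np.mean(profs, axis=0)
    bulk = mean_prof[3 : L // 2]
    assert bulk.std() < 0.02
    assert abs(bulk.mean() - 2 * n / L**3) < 0.02


def synthetic_logistic_profile(rho_dense, rho_dilute, r_mid, width, n_bins=30):
    r = np.arange(n_bins) + 0.5
    rho = rho_dilute + (rho_dense - rho_dilute) / (1 + np.exp((r - r_mid) / width))
    return RadialProfile(bin_centers=r, density={"A": rho})


def test_fit_logistic_recovers_exact_parameters():
    prof = synthetic_logistic_profile(0.55, 0.002, 9.0, 1.7)
    fit = fit_logistic(prof, "A")
    assert fit.rho_dense == pytest.approx(0.55, rel=1e-6)
    assert fit.rho_dilute == pytest.approx(0.002, rel=1e-6)
    assert fit.r_mid == pytest.approx(9.0, rel=1e-6)
    assert fit.width == pytest.approx(1.7, rel=1e-6)
    lo, hi = fit.interfacial_interval()
    assert lo < fit.r_mid < hi


def test_fit_logistic_step_function():
    r = np.arange(30) + 0.5
    rho = np.where(r < 10, 0.5, 0.001)
    prof = RadialProfile(bin_centers=r, density={"A": rho})
    fit = fit_logistic(prof, "A")
    assert abs(fit.r_mid - 10) < 1.0
    assert fit.width < 0.5


def test_fit_logistic_flat_profile_raises():
    r = np.arange(30) + 0.5
    prof = RadialProfile(bin_centers=r, density={"A": np.full(30, 0.01)})
    with pytest.raises(SinglePhaseError):
        fit_logistic(prof, "A")


def test_coexisting_concentrations_recovers_plateaus():
    profs = [synthetic_logistic_profile(0.4, 0.003, 8.0, 1.5) for _ in range(3)]
    point = coexisting_concentrations(profs, temperature=10.0)
    assert point.c_dense["A"] == pytest.approx(0.4, rel=1e-5)
    assert point.c_dilute["A"] == pytest.approx(0.003, rel=1e-4)
    assert point.se_dense["A"] == pytest.approx(0.0, abs=1e-8)
    assert point.c_dilute["A"] <= point.c_dense["A"]


def test_two_component_diagram_structure():
    from plcdmix.phase_profiler import PhasePoint

    def pt(ca_dil, cb_dil, ca_den, cb_den):
        return PhasePoint(
            temperature=10.0, species=["A", "B"],
            c_dilute={"A": ca_dil, "B": cb_dil},
            c_dense={"A": ca_den, "B": cb_den},
            se_dilute={"A": 0, "B": 0}, se_dense={"A": 0, "B": 0},
        )

    df = two_component_diagram({
        1.0: pt(2e-3, 0.0, 0.5, 0.0),
        0.5: pt(8e-4, 8e-4, 0.25, 0.25),
        0.0: pt(0.0, 3e-3, 0.0, 0.5),
    })
    assert list(df["fraction_A"]) == [0.0, 0.5, 1.0]
    pure_a = df[df["fraction_A"] == 1.0].iloc[0]
    assert pure_a["c_dilute_A"] == pytest.approx(2e-3)
    assert pure_a["c_dilute_B"] == 0.0


def test_logistic_fit_validates():
    with pytest.raises(ValueError):
        LogisticFit(0.5, 0.6, 5.0, 1.0)  # dense below dilute
    with pytest.raises(ValueError):
        LogisticFit(0.5, 0.1, 5.0, -1.0)
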