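import numpy as np
import pytest

from plcdmix.energy_model import InteractionModel, system_energy
from plcdmix.lattice_engine import (
    MOVE_KINDS,
    EnumerationTooLarge,
    PlacementError,
    RunConfig,
    energy_plateau_step,
    enumerate_exact,
    init_dense,
    metropolis_accept,
    propose_move,
    read_trajectory_text,
    run_single,
    write_trajectory_text,
)
from plcdmix.sequence_model import PolymerSpecies
from plcdmix.synthetic_data import make_enumerable_toy


@pytest.fixture
def small_config():
    """Two species, mixed attractive energies, electrostatics on."""
    model = InteractionModel(
        bead_types=("A", "B"),
        contact_energy=np.array([[-1.0, -1.5], [-1.5, -0.5]]),
        w_el=2.0,
    )
    species = [
        PolymerSpecies.homopolymer("A", "A", 4, n_chains=3, ncpr=0.2),
        PolymerSpecies.homopolymer("B", "B", 4, n_chains=3, ncpr=-0.2),
    ]
    return RunConfig(
        species=species, model=model, box=10, init_box=6,
        temperatures=(2.0,), total_steps=100_000, sample_stride=5_000,
        n_replicates=1, seed=3,
    )


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def test_init_dense_places_all_chains_in_subbox(small_config, rng):
    frame = init_dense(small_config, rng)
    frame.validate()
    lo = (10 - 6) // 2
    for _, coords in frame.chains:
        assert coords.min() >= lo and coords.max() < lo + 6
    assert frame.n_beads() == small_config.total_beads


def test_init_dense_pigeonhole_error():
    model = InteractionModel(("A",), np.array([[-1.0]]))
    sp = PolymerSpecies.homopolymer("A", "A", 28, n_chains=1)
    with pytest.raises(PlacementError):
        cfg = RunConfig(species=[sp], model=model, box=10, init_box=3,
                        temperatures=(1.0,), total_steps=0, n_replicates=1)
        init_dense(cfg, np.random.default_rng(0))


def test_init_dense_many_chains_bounded_spread(rng):
    model = InteractionModel(("A",), np.array([[-1.0]]))
    sp = PolymerSpecies.homopolymer("A", "A", 20, n_chains=40)
    cfg = RunConfig(species=[sp], model=model, box=40, init_box=16,
                    temperatures=(1.0,), total_steps=0, n_replicates=1)
    frame = init_dense(cfg, rng)
    frame.validate()
    allc = np.vstack([c for _, c in frame.chains])
    assert (allc.max(axis=0) - allc.min(axis=0) < 16).all()


# ---------------------------------------------------------------------------
# Metropolis rule
# ---------------------------------------------------------------------------


def test_metropolis_always_accepts_downhill_and_zero(rng):
    assert all(metropolis_accept(-5.0, t, rng) for t in (0.1, 1.0, 100.0))
    assert all(metropolis_accept(0.0, 1.0, rng) for _ in range(10))


def test_metropolis_rejects_nonpositive_temperature(rng):
    with pytest.raises(ValueError):
        metropolis_accept(1.0, 0.0, rng)


def test_metropolis_half_acceptance_at_ln2(rng):
    T = 2.0
    dE = T * np.log(2.0)
    acc = sum(metropolis_accept(dE, T, rng) for _ in range(4000)) / 4000
    assert abs(acc - 0.5) < 0.03


# ---------------------------------------------------------------------------
# Reference proposals
# ---------------------------------------------------------------------------


def test_local_bead_in_empty_space_is_energy_neutral(rng):
    model = InteractionModel(("A",), np.array([[-1.0]]))
    sp = PolymerSpecies.homopolymer("A", "A", 2, n_chains=1)
    cfg = RunConfig(species=[sp], model=model, box=12, init_box=4,
                    temperatures=(1.0,), total_steps=0, n_replicates=1)
    frame = init_dense(cfg, rng)
    table = {"A": 0.0}
    for _ in range(20):
        cand, dE = propose_move("local_bead", frame, model, table, rng)
        if cand is not None:
            assert dE == pytest.approx(0.0)


def test_cluster_translation_is_energy_neutral(small_config, rng):
    frame = init_dense(small_config, rng)
    table = small_config.ncpr_table()
    moved = 0
    for _ in range(30):
        cand, dE = propose_move("cluster_translation", frame, small_config.model,
                                table, rng)
        if cand is not None:
            moved += 1
            assert dE == pytest.approx(0.0, abs=1e-9)
    assert moved > 0


@pytest.mark.parametrize("kind", MOVE_KINDS)
def test_proposals_preserve_frame_invariants(kind, small_config, rng):
    frame = init_dense(small_config, rng)
    table = small_config.ncpr_table()
    accepted = 0
    # co_local demands a translation keeping both beads bonded to their
    # unmoved neighbors, so feasible proposals are rare
    for _ in range(400 if kind == "co_local" else 25):
        cand, dE = propose_move(kind, frame, small_config.model, table, rng)
        if cand is None:
            continue
        cand.validate(small_config.model.neighbor_shell)
        assert cand.n_beads() == frame.n_beads()
        assert np.isfinite(dE)
        accepted += 1
        frame = cand
    assert accepted > 0, f"{kind} never produced a feasible candidate"


# ---------------------------------------------------------------------------
# The kernel: determinism, bookkeeping, sampling correctness
# ---------------------------------------------------------------------------


def test_zero_steps_yields_initial_frame_only(small_config):
    cfg = small_config
    cfg.total_steps = 0
    traj = run_single(cfg, 2.0, seed=5)
    assert len(traj.frames) == 1
    assert traj.steps.tolist() == [0]


def test_same_seed_identical_energy_traces(small_config):
    t1 = run_single(small_config, 2.0, seed=42)
    t2 = run_single(small_config, 2.0, seed=42)
    assert np.array_equal(t1.energies, t2.energies)
    for f1, f2 in zip(t1.frames, t2.frames):
        for (l1, c1), (l2, c2) in zip(f1.chains, f2.chains):
            assert l1 == l2 and np.array_equal(c1, c2)


def test_different_seed_differs(small_config):
    t1 = run_single(small_config, 2.0, seed=1)
    t2 = run_single(small_config, 2.0, seed=2)
    assert not np.array_equal(t1.energies, t2.energies)


def test_incremental_energy_bookkeeping_closes(small_config):
    """The running energy must equal a from-scratch recomputation at every
    sample point, over all move kinds, heterospecies energies and
    electrostatics."""
    traj = run_single(small_config, 2.0, seed=9, check_bookkeeping=True)
    assert traj.bookkeeping_error < 1e-9


def test_sampled_frames_are_valid_and_energy_consistent(small_config):
    traj = run_single(small_config, 2.0, seed=11)
    table = small_config.ncpr_table()
    for frame, e in zip(traj.frames[::5], traj.energies[::5]):
        frame.validate()
        assert system_energy(frame, table, small_config.model) == pytest.approx(e)


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------


def test_enumeration_uniform_ensemble_zero_energy():
    cfg = make_enumerable_toy(1, 2, 3, 0.0, temperature=1.0)
    res = enumerate_exact(cfg, 1.0)
    assert res["mean_energy"] == pytest.approx(0.0)
    assert res["n_states"] == 26  # anchored dimer: one state per shell offset


def test_enumeration_infinite_T_matches_unweighted_average():
    hot = enumerate_exact(
        make_enumerable_toy(2, 2, 4, {("A", "B"): -1.0}), 1e9
    )
    flat = enumerate_exact(make_enumerable_toy(2, 2, 4, 0.0), 1.0)
    assert np.allclose(hot["contacts"], flat["contacts"], rtol=1e-6)


def test_enumeration_rejects_oversized_state_space():
    cfg = make_enumerable_toy(3, 4, 5, -1.0)
    with pytest.raises(EnumerationTooLarge):
        enumerate_exact(cfg, 1.0, max_states=1e6)


def test_mc_converges_to_enumeration():
    """Monte Carlo averages must match exact Boltzmann enumeration."""
    cfg = make_enumerable_toy(2, 2, 4, {("A", "A"): -0.5, ("A", "B"): -1.0,
                                        ("B", "B"): -0.2}, temperature=1.5)
    exact = enumerate_exact(cfg, 1.5)
    cfg.total_steps = 400_000
    cfg.sample_stride = 200
    means = []
    for seed in (1, 2, 3, 4):
        traj = run_single(cfg, 1.5, seed=seed)
        half = traj.steps > traj.steps[-1] / 2
        means.append(traj.energies[half].mean())
    m, se = np.mean(means), np.std(means, ddof=1) / 2
    assert abs(m - exact["mean_energy"]) < 3 * max(se, 1e-3)


# ---------------------------------------------------------------------------
# Plateau detection and I/O
# ---------------------------------------------------------------------------


def test_energy_plateau_detection():
    steps = np.arange(40) * 1000.0
    rng = np.random.default_rng(0)
    energies = np.where(steps < 15_000, -100.0 + steps * 4e-3, -40.0)
    energies = energies + rng.normal(0, 0.5, size=40)
    start = energy_plateau_step(steps, energies, window=10)
    assert start is not None and 5_000 <= start <= 25_000
    assert energy_plateau_step(steps[:5], energies[:5]) is None


def test_trajectory_text_roundtrip(small_config, tmp_path):
    traj = run_single(small_config, 2.0, seed=4)
    path = tmp_path / "t.traj.txt"
    write_trajectory_text(traj, path)
    seqs = {sp.name: sp.beads for sp in small_config.species}
    back = read_trajectory_text(path, seqs)
    assert back.temperature == traj.temperature and back.seed == traj.seed
    assert np.allclose(back.energies, traj.energies)
    assert len(back.frames) == len(traj.frames)
    for f1, f2 in zip(traj.frames, back.frames):
        assert f1.step_index == f2.step_index
        for (l1, c1), (l2, c2) in zip(f1.chains, f2.chains):
            assert l1 == l2 and np.array_equal(np.asarray(c1) % 10, c2)
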