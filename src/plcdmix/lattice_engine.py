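"""Canonical-ensemble Metropolis Monte Carlo of lattice polymers.

Multichain self-avoiding polymers live on a periodic cubic lattice, one bead
per site, vacant sites acting as implicit solvent.  Consecutive beads of a
chain occupy sites within the 26-neighbor shell (the bond convention of the
lattice-polymer lineage this engine follows); the same shell defines
nonbonded contacts, whose energies come from :mod:`plcdmix.energy_model`.
Moves are accepted with probability min[1, exp(-dE/T)] with k_B = 1.

Two execution paths are provided and tested against each other:

* a numba-compiled kernel (`run_mc` / `run_single`) that tracks the system
  energy incrementally and can verify its own bookkeeping against a full
  recompute at every sample point;
* a transparent pure-Python reference (`propose_move`, `system_energy`)
  used in tests and for pedagogy.

For tiny systems, `enumerate_exact` computes exact canonical averages by
exhaustive enumeration; the Monte Carlo sampler must converge to them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .energy_model import InteractionModel, shell_offsets, system_energy
from .sequence_model import PolymerSpecies

__all__ = [
    "Frame",
    "RunConfig",
    "Trajectory",
    "PlacementError",
    "EnumerationTooLarge",
    "MOVE_KINDS",
    "init_dense",
    "metropolis_accept",
    "propose_move",
    "run_single",
    "run_mc",
    "enumerate_exact",
    "contact_matrix",
    "energy_plateau_step",
    "write_energy_trace",
    "write_trajectory_text",
    "read_trajectory_text",
]

MOVE_KINDS = (
    "local_bead",
    "slithering_snake",
    "chain_translation",
    "pivot",
    "double_pivot",
    "co_local",
    "cluster_translation",
)


class PlacementError(RuntimeError):
    """Dense initialization could not place all chains; enlarge init_box."""


class EnumerationTooLarge(RuntimeError):
    """The exact-enumeration state space exceeds the configured limit."""


# The 48 point-group symmetries of the cubic lattice (rotations+reflections),
# used by pivot moves; closed under inverses, so uniform selection is a
# symmetric proposal.
_ROTATIONS = np.array(
    [
        np.array([[1 if c == p else 0 for c in range(3)] for p in perm]) * np.array(signs)[:, None]
        for perm in itertools.permutations(range(3))
        for signs in itertools.product((1, -1), repeat=3)
    ],
    dtype=np.int64,
)


# ---------------------------------------------------------------------------
# Frames and configuration
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """Lattice occupancy: per-chain ordered bead coordinates plus box.

    ``chains`` is a list of ``(species_label, coords)`` with coords of shape
    (n_beads, 3); ``sequences`` maps species label -> bead-type codes so the
    frame is self-describing for energy evaluation.
    """

    box: tuple[int, int, int]
    chains: list
    sequences: dict
    step_index: int = 0
    dispersed_flag: bool = False

    def bead_type(self, chain_index: int, bead_index: int) -> str:
        label = self.chains[chain_index][0]
        return self.sequences[label][bead_index]

    def n_beads(self) -> int:
        return sum(len(c[1]) for c in self.chains)

    def validate(self, neighbor_shell: int = 26) -> None:
        """Check self-avoidance and the bond convention; raise on violation."""
        box = np.asarray(self.box)
        seen = set()
        for label, coords in self.chains:
            coords = np.asarray(coords) % box
            for xyz in coords:
                key = tuple(int(v) for v in xyz)
                if key in seen:
                    raise ValueError(f"overlapping beads at {key}")
                seen.add(key)
            d = np.abs(np.diff(coords, axis=0))
            d = np.minimum(d, box - d)
            if len(coords) > 1 and (d.max(axis=1) != 1).any():
                raise ValueError(f"broken bond in a chain of species {label!r}")

    def copy(self) -> "Frame":
        return Frame(
            box=self.box,
            chains=[(lab, np.array(c)) for lab, c in self.chains],
            sequences=self.sequences,
            step_index=self.step_index,
            dispersed_flag=self.dispersed_flag,
        )


def _normalize_box(box) -> tuple[int, int, int]:
    if np.isscalar(box):
        return (int(box),) * 3
    t = tuple(int(v) for v in box)
    if len(t) != 3:
        raise ValueError("box must be an int or a length-3 tuple")
    return t


@dataclass
class RunConfig:
    """Everything needed to run one simulation campaign.

    Temperatures are in reduced units (k_B = 1).  The default geometry
    follows the dense-seed protocol: chains start inside a central
    ``init_box``^3 subregion of the full box so a condensate forms quickly,
    and the dilute phase develops by evaporation.
    """

    species: list
    model: InteractionModel
    box: tuple[int, int, int] = (48, 48, 48)
    init_box: int = 35
    temperatures: tuple = (50.0,)
    total_steps: int = 1_000_000
    sample_stride: int | None = None
    move_weights: dict | None = None
    n_replicates: int = 5
    seed: int = 0
    analysis_fraction: float = 0.5  # analyze the second half of the run

    def __post_init__(self) -> None:
        self.box = _normalize_box(self.box)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.total_steps < 0:
            raise ValueError("total_steps must be non-negative")
        if self.init_box > min(self.box):
            raise ValueError("init_box cannot exceed the box")
        if self.move_weights:
            unknown = set(self.move_weights) - set(MOVE_KINDS)
            if unknown:
                raise ValueError(f"unknown move kinds: {sorted(unknown)}")

    @property
    def total_beads(self) -> int:
        return sum(sp.n_residues * sp.n_chains for sp in self.species)

    @property
    def volume_fraction(self) -> float:
        """Target total bead volume fraction (paper-style bookkeeping)."""
        v = self.box[0] * self.box[1] * self.box[2]
        return self.total_beads / v

    def stride(self) -> int:
        if self.sample_stride is not None:
            return max(1, int(self.sample_stride))
        return max(1, self.total_steps // 50)

    def replicate_seed(self, t_index: int, replicate: int) -> int:
        """Distinct, recorded seed per (temperature, replicate)."""
        return int((self.seed * 1_000_003 + t_index * 7919 + replicate * 104729 + 1) % (2**31 - 1))

    def ncpr_table(self) -> dict:
        return {sp.name: sp.ncpr for sp in self.species}


@dataclass
class Trajectory:
    """Sampled frames plus the energy trace of one (T, replicate) run."""

    temperature: float
    replicate: int
    seed: int
    frames: list
    steps: np.ndarray
    energies: np.ndarray
    acceptance_rate: float
    bookkeeping_error: float
    analysis_fraction: float = 0.5

    def analysis_frames(self) -> list:
        """Frames in the analysis window (the final portion of the run)."""
        if len(self.frames) == 1:
            return list(self.frames)
        last_step = self.frames[-1].step_index
        cut = (1.0 - self.analysis_fraction) * last_step
        out = [f for f in self.frames if f.step_index > cut or f.step_index == last_step]
        return out if out else [self.frames[-1]]


# ---------------------------------------------------------------------------
# Dense-seed initialization
# ---------------------------------------------------------------------------


def init_dense(config: RunConfig, rng: np.random.Generator) -> Frame:
    """Grow all chains as self-avoiding walks inside the central subbox.

    Chains are placed longest-first; each chain is retried from a fresh
    start on dead ends, and the whole frame is retried a bounded number of
    times before giving up with a :class:`PlacementError`.
    """
    box = config.box
    b = config.init_box
    if config.total_beads > b**3:
        raise PlacementError(
            f"{config.total_beads} beads cannot fit in init_box {b}^3 = {b**3};"
            " increase init_box"
        )
    lo = np.array([(L - b) // 2 for L in box])
    offs = shell_offsets(config.model.neighbor_shell)
    chain_specs = []
    for sp in config.species:
        chain_specs.extend([(sp.name, sp.n_residues)] * sp.n_chains)
    chain_specs.sort(key=lambda t: -t[1])

    for _attempt in range(20):
        occupied: set = set()
        chains = []
        failed = False
        for label, n in chain_specs:
            placed = None
            for _retry in range(200):
                start = lo + rng.integers(0, b, size=3)
                key = tuple(int(v) for v in start)
                if key in occupied:
                    continue
                walk = [start]
                taken = {key}
                while len(walk) < n:
                    order = rng.permutation(len(offs))
                    for oi in order:
                        nxt = walk[-1] + offs[oi]
                        if np.any(nxt < lo) or np.any(nxt >= lo + b):
                            continue
                        k2 = tuple(int(v) for v in nxt)
                        if k2 in occupied or k2 in taken:
                            continue
                        walk.append(nxt)
                        taken.add(k2)
                        break
                    else:
                        break  # dead end
                if len(walk) == n:
                    placed = np.array(walk, dtype=np.int64)
                    occupied |= taken
                    break
            if placed is None:
                failed = True
                break
            chains.append((label, placed))
        if not failed:
            sequences = {sp.name: sp.beads for sp in config.species}
            # restore species grouping order for reproducible chain indexing
            order = {sp.name: i for i, sp in enumerate(config.species)}
            chains.sort(key=lambda c: order[c[0]])
            frame = Frame(box=box, chains=chains, sequences=sequences)
            frame.validate(config.model.neighbor_shell)
            return frame
    raise PlacementError(
        f"failed to place chains after bounded retries; increase init_box (= {b})"
    )


def metropolis_accept(delta_E: float, T: float, rng: np.random.Generator) -> bool:
    """Accept with probability min[1, exp(-delta_E / T)] (k_B = 1)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_E <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_E / T))


# ---------------------------------------------------------------------------
# Pure-Python reference proposals
# ---------------------------------------------------------------------------


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return (d + box // 2) % box - box // 2


def _unwrap_chain(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    out = np.array(coords, dtype=np.int64)
    for i in range(1, len(out)):
        step = _min_image(coords[i] - coords[i - 1], box)
        out[i] = out[i - 1] + step
    return out


def propose_move(kind: str, frame: Frame, model: InteractionModel,
                 species_table: dict, rng: np.random.Generator):
    """Reference implementation of one move proposal.

    Returns ``(candidate_frame, delta_E)`` or ``(None, 0.0)`` when the
    proposal is infeasible (counted as a rejected move).  delta_E is obtained
    by full energy recomputation; the production kernel computes the same
    quantity incrementally.
    """
    if kind not in MOVE_KINDS:
        raise ValueError(f"unknown move kind {kind!r}")
    box = np.asarray(frame.box, dtype=np.int64)
    offs = model.offsets()
    cand = frame.copy()
    occupied = {
        tuple(int(v) for v in xyz): (ci, bi)
        for ci, (_, coords) in enumerate(frame.chains)
        for bi, xyz in enumerate(np.asarray(coords) % box)
    }
    n_chains = len(frame.chains)
    ci = int(rng.integers(n_chains))
    label, coords = cand.chains[ci]
    coords = np.array(coords) % box
    n = len(coords)

    def bond_ok(a, b):
        d = np.abs(_min_image(a - b, box))
        return d.max() == 1

    ok = False
    if kind == "local_bead":
        bi = int(rng.integers(n))
        new = (coords[bi] + offs[int(rng.integers(len(offs)))]) % box
        key = tuple(int(v) for v in new)
        ok = key not in occupied
        if ok and bi > 0:
            ok = bond_ok(new, coords[bi - 1])
        if ok and bi < n - 1:
            ok = bond_ok(new, coords[bi + 1])
        if ok:
            coords[bi] = new
    elif kind == "slithering_snake":
        head = bool(rng.integers(2))
        off = offs[int(rng.integers(len(offs)))]
        if head:
            new_end = (coords[-1] + off) % box
            shifted = np.vstack([coords[1:], new_end])
        else:
            new_end = (coords[0] + off) % box
            shifted = np.vstack([new_end, coords[:-1]])
        key = tuple(int(v) for v in new_end)
        hit = occupied.get(key)
        vacated = (ci, 0) if head else (ci, n - 1)
        ok = hit is None or hit == vacated
        if ok:
            coords = shifted
    elif kind == "chain_translation":
        shift = rng.integers(-2, 3, size=3)
        if not shift.any():
            ok = False
        else:
            newc = (coords + shift) % box
            ok = all(
                occupied.get(tuple(int(v) for v in p), (ci, -1))[0] == ci
                for p in newc
            )
            if ok:
                coords = newc
    elif kind in ("pivot", "double_pivot"):
        u = _unwrap_chain(coords, box)
        if kind == "pivot":
            p = int(rng.integers(n))
            after = bool(rng.integers(2))
            R = _ROTATIONS[int(rng.integers(len(_ROTATIONS)))]
            seg = slice(p + 1, n) if after else slice(0, p)
            u[seg] = u[p] + (u[seg] - u[p]) @ R.T
        else:
            if n < 3:
                return None, 0.0
            i = int(rng.integers(n - 2))
            j = int(rng.integers(i + 2, n))
            c = u[i] + u[j]
            u[i + 1 : j] = c - u[i + 1 : j][::-1]
        newc = u % box
        moved = {tuple(int(v) for v in p) for p in newc}
        if len(moved) == n:
            ok = all(
                occupied.get(s, (ci, -1))[0] == ci for s in moved
            )
        if ok:
            coords = newc
    elif kind == "co_local":
        bi = int(rng.integers(n))
        partner_site = tuple(
            int(v) for v in (coords[bi] + offs[int(rng.integers(len(offs)))]) % box
        )
        hit = occupied.get(partner_site)
        if hit is None:
            return None, 0.0
        cj, bj = hit
        shift = offs[int(rng.integers(len(offs)))]
        moved = {(ci, bi), (cj, bj)}
        newpos = {}
        for (ck, bk) in moved:
            p = (np.asarray(cand.chains[ck][1])[bk] + shift) % box
            newpos[(ck, bk)] = p
        ok = True
        for (ck, bk), p in newpos.items():
            hit = occupied.get(tuple(int(v) for v in p))
            if hit is not None and hit not in moved:
                ok = False
        if ok:
            for (ck, bk), p in newpos.items():
                cc = np.array(np.asarray(cand.chains[ck][1]) % box)
                cc[bk] = p
                cand.chains[ck] = (cand.chains[ck][0], cc)
                nk = len(cc)
                if bk > 0 and not bond_ok(cc[bk], cc[bk - 1]):
                    ok = False
                if bk < nk - 1 and not bond_ok(cc[bk], cc[bk + 1]):
                    ok = False
        if ok:
            e0 = system_energy(frame, species_table, model)
            e1 = system_energy(cand, species_table, model)
            cand.step_index = frame.step_index + 1
            return cand, e1 - e0
        return None, 0.0
    elif kind == "cluster_translation":
        from .phase_profiler import chain_adjacency

        adj = chain_adjacency(frame, model.neighbor_shell)
        cluster = {ci}
        stack = [ci]
        while stack:
            c = stack.pop()
            for c2 in np.flatnonzero(adj[c]):
                if c2 not in cluster:
                    cluster.add(int(c2))
                    stack.append(int(c2))
        shift = offs[int(rng.integers(len(offs)))]
        newsets = {}
        ok = True
        for ck in cluster:
            cc = (np.asarray(cand.chains[ck][1]) + shift) % box
            newsets[ck] = cc
            for p in cc:
                hit = occupied.get(tuple(int(v) for v in p))
                if hit is not None and hit[0] not in cluster:
                    ok = False
        if ok:
            for ck, cc in newsets.items():
                cand.chains[ck] = (cand.chains[ck][0], cc)
            # reject if the rigid shift created new external contacts
            adj2 = chain_adjacency(cand, model.neighbor_shell)
            for ck in cluster:
                for c2 in np.flatnonzero(adj2[ck]):
                    if int(c2) not in cluster:
                        ok = False
        if ok:
            cand.step_index = frame.step_index + 1
            return cand, 0.0
        return None, 0.0

    if not ok:
        return None, 0.0
    cand.chains[ci] = (label, coords)
    try:
        cand.validate(model.neighbor_shell)
    except ValueError:
        return None, 0.0
    e0 = system_energy(frame, species_table, model)
    e1 = system_energy(cand, species_table, model)
    cand.step_index = frame.step_index + 1
    return cand, e1 - e0


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _site(x, y, z, Ly, Lz):
    return (x * Ly + y) * Lz + z


@njit(cache=True, inline="always")
def _adjacent(ax, ay, az, bx, by, bz, Lx, Ly, Lz):
    dx = abs(ax - bx)
    if dx > Lx - dx:
        dx = Lx - dx
    dy = abs(ay - by)
    if dy > Ly - dy:
        dy = Ly - dy
    dz = abs(az - bz)
    if dz > Lz - dz:
        dz = Lz - dz
    m = dx
    if dy > m:
        m = dy
    if dz > m:
        m = dz
    return m == 1


@njit(cache=True)
def _full_energy(coords, grid, box, offsets, bead_type, bead_chain,
                 chain_species, e_contact, elec, bonded_excluded):
    E = 0.0
    n = coords.shape[0]
    for b in range(n):
        x, y, z = coords[b, 0], coords[b, 1], coords[b, 2]
        tb = bead_type[b]
        sb = chain_species[bead_chain[b]]
        for o in range(offsets.shape[0]):
            nx = (x + offsets[o, 0]) % box[0]
            ny = (y + offsets[o, 1]) % box[1]
            nz = (z + offsets[o, 2]) % box[2]
            g = grid[_site(nx, ny, nz, box[1], box[2])]
            if g == 0:
                continue
            j = g - 1
            if j <= b:
                continue
            if bonded_excluded and bead_chain[j] == bead_chain[b] and j == b + 1:
                continue
            E += e_contact[tb, bead_type[j]] + elec[sb, chain_species[bead_chain[j]]]
    return E


@njit(cache=True)
def _site_energy(x, y, z, t, s, excl, grid, box, offsets, bead_type,
                 bead_chain, chain_species, e_contact, elec):
    """Contact energy a bead of (type t, species s) collects at one site,
    excluding the single bead index ``excl`` (its bond partner)."""
    E = 0.0
    for o in range(offsets.shape[0]):
        nx = (x + offsets[o, 0]) % box[0]
        ny = (y + offsets[o, 1]) % box[1]
        nz = (z + offsets[o, 2]) % box[2]
        g = grid[_site(nx, ny, nz, box[1], box[2])]
        if g == 0:
            continue
        j = g - 1
        if j == excl:
            continue
        E += e_contact[t, bead_type[j]] + elec[s, chain_species[bead_chain[j]]]
    return E


@njit(cache=True)
def _moved_energy(idxs, k, pos, grid, mark, box, offsets, bead_type, bead_chain,
                  chain_species, e_contact, elec, bonded_excluded):
    E = 0.0
    for a in range(k):
        b = idxs[a]
        x, y, z = pos[a, 0], pos[a, 1], pos[a, 2]
        tb = bead_type[b]
        sb = chain_species[bead_chain[b]]
        for o in range(offsets.shape[0]):
            nx = (x + offsets[o, 0]) % box[0]
            ny = (y + offsets[o, 1]) % box[1]
            nz = (z + offsets[o, 2]) % box[2]
            g = grid[_site(nx, ny, nz, box[1], box[2])]
            if g == 0:
                continue
            j = g - 1
            if j == b:
                continue
            if bonded_excluded and bead_chain[j] == bead_chain[b] and (j == b + 1 or j == b - 1):
                continue
            e = e_contact[tb, bead_type[j]] + elec[sb, chain_species[bead_chain[j]]]
            if mark[j] == 1:
                E += 0.5 * e
            else:
                E += e
    return E


@njit(cache=True)
def _run_kernel(coords, box, chain_start, chain_len, chain_homo, bead_chain,
                bead_type, chain_species, e_contact, elec, offsets, rotations,
                move_ids, move_cum, bonded_excluded, T, n_steps, seed,
                stride, check_book, frames_out, energies_out, steps_out):
    np.random.seed(seed)
    n_beads = coords.shape[0]
    n_chains = chain_start.shape[0]
    Lx, Ly, Lz = box[0], box[1], box[2]
    grid = np.zeros(Lx * Ly * Lz, dtype=np.int64)
    for b in range(n_beads):
        grid[_site(coords[b, 0], coords[b, 1], coords[b, 2], Ly, Lz)] = b + 1

    E = _full_energy(coords, grid, box, offsets, bead_type, bead_chain,
                     chain_species, e_contact, elec, bonded_excluded)

    idxs = np.empty(n_beads, dtype=np.int64)
    oldpos = np.empty((n_beads, 3), dtype=np.int64)
    newpos = np.empty((n_beads, 3), dtype=np.int64)
    unwrapped = np.empty((n_beads, 3), dtype=np.int64)
    mark = np.zeros(n_beads, dtype=np.uint8)
    cl_mark = np.zeros(n_chains, dtype=np.uint8)
    cl_stack = np.empty(n_chains, dtype=np.int64)
    n_accept = 0
    book_err = 0.0
    sample = 0
    n_moves = move_cum.shape[0]

    for step in range(1, n_steps + 1):
        u = np.random.random()
        kind = move_ids[0]
        for m in range(n_moves):
            if u <= move_cum[m]:
                kind = move_ids[m]
                break
        ci = np.random.randint(0, n_chains)
        s0 = chain_start[ci]
        n = chain_len[ci]
        k = 0
        feasible = True
        zero_de = False  # cluster moves are energy-neutral by construction

        if kind == 0:  # local_bead
            bi = s0 + np.random.randint(0, n)
            o = np.random.randint(0, offsets.shape[0])
            nx = (coords[bi, 0] + offsets[o, 0]) % Lx
            ny = (coords[bi, 1] + offsets[o, 1]) % Ly
            nz = (coords[bi, 2] + offsets[o, 2]) % Lz
            if bi > s0 and not _adjacent(nx, ny, nz, coords[bi - 1, 0], coords[bi - 1, 1], coords[bi - 1, 2], Lx, Ly, Lz):
                feasible = False
            if feasible and bi < s0 + n - 1 and not _adjacent(nx, ny, nz, coords[bi + 1, 0], coords[bi + 1, 1], coords[bi + 1, 2], Lx, Ly, Lz):
                feasible = False
            if feasible:
                idxs[0] = bi
                newpos[0, 0], newpos[0, 1], newpos[0, 2] = nx, ny, nz
                k = 1
        elif kind == 1 and chain_homo[ci] == 1 and bonded_excluded:
            # homopolymer reptation: only the two end sites change the
            # type-at-site pattern, so dE is computed from those sites alone
            head = np.random.randint(0, 2)
            o = np.random.randint(0, offsets.shape[0])
            if head == 1:
                vac = s0          # tail bead vacates its site
                anchor = s0 + n - 1  # new end bonds to the old head bead
            else:
                vac = s0 + n - 1
                anchor = s0
            vx, vy, vz = coords[vac, 0], coords[vac, 1], coords[vac, 2]
            nx = (coords[anchor, 0] + offsets[o, 0]) % Lx
            ny = (coords[anchor, 1] + offsets[o, 1]) % Ly
            nz = (coords[anchor, 2] + offsets[o, 2]) % Lz
            t = bead_type[vac]
            sp = chain_species[ci]
            bond_old = vac + 1 if head == 1 else vac - 1
            E_old = _site_energy(vx, vy, vz, t, sp, bond_old, grid, box,
                                 offsets, bead_type, bead_chain,
                                 chain_species, e_contact, elec)
            grid[_site(vx, vy, vz, Ly, Lz)] = 0
            if grid[_site(nx, ny, nz, Ly, Lz)] != 0:
                grid[_site(vx, vy, vz, Ly, Lz)] = vac + 1
            else:
                E_new = _site_energy(nx, ny, nz, t, sp, anchor, grid, box,
                                     offsets, bead_type, bead_chain,
                                     chain_species, e_contact, elec)
                dE = E_new - E_old
                if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                    if head == 1:
                        for a in range(n - 1):
                            b = s0 + a
                            coords[b, 0] = coords[b + 1, 0]
                            coords[b, 1] = coords[b + 1, 1]
                            coords[b, 2] = coords[b + 1, 2]
                            grid[_site(coords[b, 0], coords[b, 1], coords[b, 2], Ly, Lz)] = b + 1
                        last = s0 + n - 1
                        coords[last, 0], coords[last, 1], coords[last, 2] = nx, ny, nz
                        grid[_site(nx, ny, nz, Ly, Lz)] = last + 1
                    else:
                        for a in range(n - 1, 0, -1):
                            b = s0 + a
                            coords[b, 0] = coords[b - 1, 0]
                            coords[b, 1] = coords[b - 1, 1]
                            coords[b, 2] = coords[b - 1, 2]
                            grid[_site(coords[b, 0], coords[b, 1], coords[b, 2], Ly, Lz)] = b + 1
                        coords[s0, 0], coords[s0, 1], coords[s0, 2] = nx, ny, nz
                        grid[_site(nx, ny, nz, Ly, Lz)] = s0 + 1
                    E += dE
                    n_accept += 1
                else:
                    grid[_site(vx, vy, vz, Ly, Lz)] = vac + 1
            k = 0
            feasible = False  # handled entirely above
        elif kind == 1:  # slithering_snake (general chains)
            head = np.random.randint(0, 2)
            o = np.random.randint(0, offsets.shape[0])
            k = n
            if head == 1:
                for a in range(n - 1):
                    idxs[a] = s0 + a
                    newpos[a, 0] = coords[s0 + a + 1, 0]
                    newpos[a, 1] = coords[s0 + a + 1, 1]
                    newpos[a, 2] = coords[s0 + a + 1, 2]
                idxs[n - 1] = s0 + n - 1
                newpos[n - 1, 0] = (coords[s0 + n - 1, 0] + offsets[o, 0]) % Lx
                newpos[n - 1, 1] = (coords[s0 + n - 1, 1] + offsets[o, 1]) % Ly
                newpos[n - 1, 2] = (coords[s0 + n - 1, 2] + offsets[o, 2]) % Lz
            else:
                for a in range(1, n):
                    idxs[a] = s0 + a
                    newpos[a, 0] = coords[s0 + a - 1, 0]
                    newpos[a, 1] = coords[s0 + a - 1, 1]
                    newpos[a, 2] = coords[s0 + a - 1, 2]
                idxs[0] = s0
                newpos[0, 0] = (coords[s0, 0] + offsets[o, 0]) % Lx
                newpos[0, 1] = (coords[s0, 1] + offsets[o, 1]) % Ly
                newpos[0, 2] = (coords[s0, 2] + offsets[o, 2]) % Lz
        elif kind == 2:  # chain_translation
            sx = np.random.randint(-2, 3)
            sy = np.random.randint(-2, 3)
            sz = np.random.randint(-2, 3)
            if sx == 0 and sy == 0 and sz == 0:
                feasible = False
            else:
                k = n
                for a in range(n):
                    idxs[a] = s0 + a
                    newpos[a, 0] = (coords[s0 + a, 0] + sx) % Lx
                    newpos[a, 1] = (coords[s0 + a, 1] + sy) % Ly
                    newpos[a, 2] = (coords[s0 + a, 2] + sz) % Lz
        elif kind == 3 or kind == 4:  # pivot / double_pivot
            # unwrap the chain once
            unwrapped[0, 0] = coords[s0, 0]
            unwrapped[0, 1] = coords[s0, 1]
            unwrapped[0, 2] = coords[s0, 2]
            for a in range(1, n):
                for d in range(3):
                    L = box[d]
                    dd = coords[s0 + a, d] - coords[s0 + a - 1, d]
                    dd = (dd + L // 2) % L - L // 2
                    unwrapped[a, d] = unwrapped[a - 1, d] + dd
            if kind == 3:
                p = np.random.randint(0, n)
                after = np.random.randint(0, 2)
                r = np.random.randint(0, rotations.shape[0])
                if r == 0:
                    feasible = False  # identity rotation: a no-op proposal
                if after == 1:
                    lo, hi = p + 1, n
                else:
                    lo, hi = 0, p
                k = hi - lo
                if k == 0 or not feasible:
                    feasible = False
                    k = 0
                for a in range(k):
                    src = lo + a
                    idxs[a] = s0 + src
                    for d in range(3):
                        v = 0
                        for e in range(3):
                            v += rotations[r, d, e] * (unwrapped[src, e] - unwrapped[p, e])
                        newpos[a, d] = (unwrapped[p, d] + v) % box[d]
            else:
                if n < 3:
                    feasible = False
                else:
                    i = np.random.randint(0, n - 2)
                    j = np.random.randint(i + 2, n)
                    k = j - i - 1
                    for a in range(k):
                        src = i + 1 + a
                        mirror = i + j - src
                        idxs[a] = s0 + src
                        for d in range(3):
                            c = unwrapped[i, d] + unwrapped[j, d]
                            newpos[a, d] = (c - unwrapped[mirror, d]) % box[d]
        elif kind == 5:  # co_local: translate a bead and one shell partner
            bi = s0 + np.random.randint(0, n)
            o1 = np.random.randint(0, offsets.shape[0])
            px = (coords[bi, 0] + offsets[o1, 0]) % Lx
            py = (coords[bi, 1] + offsets[o1, 1]) % Ly
            pz = (coords[bi, 2] + offsets[o1, 2]) % Lz
            g = grid[_site(px, py, pz, Ly, Lz)]
            if g == 0:
                feasible = False
            else:
                bj = g - 1
                o2 = np.random.randint(0, offsets.shape[0])
                idxs[0] = bi
                idxs[1] = bj
                k = 2
                for a in range(2):
                    bb = idxs[a]
                    newpos[a, 0] = (coords[bb, 0] + offsets[o2, 0]) % Lx
                    newpos[a, 1] = (coords[bb, 1] + offsets[o2, 1]) % Ly
                    newpos[a, 2] = (coords[bb, 2] + offsets[o2, 2]) % Lz
                # bond checks against unmoved bonded neighbors
                for a in range(2):
                    bb = idxs[a]
                    other = idxs[1 - a]
                    cc = bead_chain[bb]
                    for nb in (bb - 1, bb + 1):
                        if nb < 0 or nb >= n_beads or bead_chain[nb] != cc:
                            continue
                        if nb == other:
                            continue  # both move rigidly; bond preserved
                        if not _adjacent(newpos[a, 0], newpos[a, 1], newpos[a, 2],
                                         coords[nb, 0], coords[nb, 1], coords[nb, 2],
                                         Lx, Ly, Lz):
                            feasible = False
        else:  # cluster_translation
            for c in range(n_chains):
                cl_mark[c] = 0
            cl_mark[ci] = 1
            cl_stack[0] = ci
            top = 1
            while top > 0:
                top -= 1
                c = cl_stack[top]
                for a in range(chain_len[c]):
                    b = chain_start[c] + a
                    x, y, z = coords[b, 0], coords[b, 1], coords[b, 2]
                    for o in range(offsets.shape[0]):
                        nx = (x + offsets[o, 0]) % Lx
                        ny = (y + offsets[o, 1]) % Ly
                        nz = (z + offsets[o, 2]) % Lz
                        g = grid[_site(nx, ny, nz, Ly, Lz)]
                        if g == 0:
                            continue
                        c2 = bead_chain[g - 1]
                        if cl_mark[c2] == 0:
                            cl_mark[c2] = 1
                            cl_stack[top] = c2
                            top += 1
            o = np.random.randint(0, offsets.shape[0])
            k = 0
            for c in range(n_chains):
                if cl_mark[c] == 0:
                    continue
                for a in range(chain_len[c]):
                    b = chain_start[c] + a
                    idxs[k] = b
                    newpos[k, 0] = (coords[b, 0] + offsets[o, 0]) % Lx
                    newpos[k, 1] = (coords[b, 1] + offsets[o, 1]) % Ly
                    newpos[k, 2] = (coords[b, 2] + offsets[o, 2]) % Lz
                    k += 1
            zero_de = True
            if k == n_beads:
                # moving everything is a no-op for sampling; accept cheaply
                for a in range(k):
                    b = idxs[a]
                    grid[_site(coords[b, 0], coords[b, 1], coords[b, 2], Ly, Lz)] = 0
                for a in range(k):
                    b = idxs[a]
                    coords[b, 0] = newpos[a, 0]
                    coords[b, 1] = newpos[a, 1]
                    coords[b, 2] = newpos[a, 2]
                    grid[_site(newpos[a, 0], newpos[a, 1], newpos[a, 2], Ly, Lz)] = b + 1
                n_accept += 1
                k = 0
                feasible = False  # already handled

        accepted = False
        if feasible and k > 0:
            for a in range(k):
                mark[idxs[a]] = 1
                oldpos[a, 0] = coords[idxs[a], 0]
                oldpos[a, 1] = coords[idxs[a], 1]
                oldpos[a, 2] = coords[idxs[a], 2]
            if zero_de:
                E_old = 0.0
            else:
                E_old = _moved_energy(idxs, k, oldpos, grid, mark, box, offsets,
                                      bead_type, bead_chain, chain_species,
                                      e_contact, elec, bonded_excluded)
            for a in range(k):
                grid[_site(oldpos[a, 0], oldpos[a, 1], oldpos[a, 2], Ly, Lz)] = 0
            placed = 0
            collision = False
            for a in range(k):
                s = _site(newpos[a, 0], newpos[a, 1], newpos[a, 2], Ly, Lz)
                if grid[s] != 0:
                    collision = True
                    break
                grid[s] = idxs[a] + 1
                placed += 1
            if not collision:
                if zero_de:
                    # reject if the rigid cluster shift created external contacts
                    ext = False
                    for a in range(k):
                        x, y, z = newpos[a, 0], newpos[a, 1], newpos[a, 2]
                        for o in range(offsets.shape[0]):
                            nx = (x + offsets[o, 0]) % Lx
                            ny = (y + offsets[o, 1]) % Ly
                            nz = (z + offsets[o, 2]) % Lz
                            g = grid[_site(nx, ny, nz, Ly, Lz)]
                            if g != 0 and mark[g - 1] == 0:
                                ext = True
                                break
                        if ext:
                            break
                    accepted = not ext
                else:
                    E_new = _moved_energy(idxs, k, newpos, grid, mark, box, offsets,
                                          bead_type, bead_chain, chain_species,
                                          e_contact, elec, bonded_excluded)
                    dE = E_new - E_old
                    if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                        accepted = True
                        E += dE
            if accepted:
                for a in range(k):
                    b = idxs[a]
                    coords[b, 0] = newpos[a, 0]
                    coords[b, 1] = newpos[a, 1]
                    coords[b, 2] = newpos[a, 2]
                n_accept += 1
            else:
                for a in range(placed):
                    grid[_site(newpos[a, 0], newpos[a, 1], newpos[a, 2], Ly, Lz)] = 0
                for a in range(k):
                    grid[_site(oldpos[a, 0], oldpos[a, 1], oldpos[a, 2], Ly, Lz)] = idxs[a] + 1
            for a in range(k):
                mark[idxs[a]] = 0

        if stride > 0 and step % stride == 0 and sample < frames_out.shape[0]:
            for b in range(n_beads):
                frames_out[sample, b, 0] = coords[b, 0]
                frames_out[sample, b, 1] = coords[b, 1]
                frames_out[sample, b, 2] = coords[b, 2]
            energies_out[sample] = E
            steps_out[sample] = step
            if check_book:
                E_chk = _full_energy(coords, grid, box, offsets, bead_type,
                                     bead_chain, chain_species, e_contact,
                                     elec, bonded_excluded)
                err = abs(E_chk - E)
                if err > book_err:
                    book_err = err
            sample += 1

    return E, book_err, n_accept, sample


# ---------------------------------------------------------------------------
# Array packing and the public run functions
# ---------------------------------------------------------------------------


def _pack(frame: Frame, config: RunConfig):
    model = config.model
    species_names = [sp.name for sp in config.species]
    sp_index = {name: i for i, name in enumerate(species_names)}
    n_chains = len(frame.chains)
    chain_len = np.array([len(c[1]) for c in frame.chains], dtype=np.int64)
    chain_start = np.concatenate([[0], np.cumsum(chain_len)[:-1]]).astype(np.int64)
    n_beads = int(chain_len.sum())
    coords = np.vstack([np.asarray(c[1]) % np.asarray(frame.box) for c in frame.chains]).astype(np.int64)
    bead_chain = np.repeat(np.arange(n_chains, dtype=np.int64), chain_len)
    chain_species = np.array([sp_index[c[0]] for c in frame.chains], dtype=np.int64)
    bead_type = np.empty(n_beads, dtype=np.int64)
    for ci, (label, _) in enumerate(frame.chains):
        seq = frame.sequences[label]
        for bi in range(chain_len[ci]):
            bead_type[chain_start[ci] + bi] = model.type_index(seq[bi])
    chain_homo = np.array(
        [1 if len(set(frame.sequences[c[0]])) == 1 else 0 for c in frame.chains],
        dtype=np.int64,
    )
    ncprs = np.array([sp.ncpr for sp in config.species])
    elec = model.w_el * (0.5 * (ncprs[:, None] + ncprs[None, :])) ** 2
    return (coords, chain_start, chain_len, chain_homo, bead_chain, bead_type,
            chain_species, elec)


# Default move mix: mostly cheap single-bead moves, chain-scale moves at
# moderate frequency, and rare whole-cluster translations (each proposal of
# the latter costs O(cluster size)).  Config-overridable.
DEFAULT_MOVE_WEIGHTS = {
    "local_bead": 0.55,
    "slithering_snake": 0.30,
    "chain_translation": 0.02,
    "pivot": 0.04,
    "double_pivot": 0.03,
    "co_local": 0.05,
    "cluster_translation": 0.003,
}


def _move_arrays(config: RunConfig, n_max_chain: int):
    weights = dict(DEFAULT_MOVE_WEIGHTS)
    if config.move_weights is not None:
        weights = dict(config.move_weights)
    ids, w = [], []
    for i, kind in enumerate(MOVE_KINDS):
        wt = float(weights.get(kind, 0.0))
        if wt > 0:
            ids.append(i)
            w.append(wt)
    if not ids:
        raise ValueError("at least one move kind must have positive weight")
    w = np.array(w)
    return np.array(ids, dtype=np.int64), np.cumsum(w / w.sum())


def run_single(config: RunConfig, temperature: float, seed: int,
               start_frame: Frame | None = None,
               check_bookkeeping: bool = False) -> Trajectory:
    """Run one replicate at one temperature; reproducible from (config, seed)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    frame0 = start_frame.copy() if start_frame is not None else init_dense(config, rng)
    (coords, chain_start, chain_len, chain_homo, bead_chain, bead_type,
     chain_species, elec) = _pack(frame0, config)
    model = config.model
    stride = config.stride()
    n_samples = config.total_steps // stride if config.total_steps else 0
    n_beads = coords.shape[0]
    frames_out = np.zeros((n_samples, n_beads, 3), dtype=np.int64)
    energies_out = np.zeros(n_samples)
    steps_out = np.zeros(n_samples, dtype=np.int64)
    move_ids, move_cum = _move_arrays(config, int(chain_len.max()))
    box = np.array(frame0.box, dtype=np.int64)
    offsets = shell_offsets(model.neighbor_shell)
    E_final, book_err, n_accept, n_got = _run_kernel(
        coords, box, chain_start, chain_len, chain_homo, bead_chain, bead_type,
        chain_species, model.contact_energy, elec, offsets, _ROTATIONS,
        move_ids, move_cum, model.bonded_excluded, float(temperature),
        int(config.total_steps), int(seed % (2**31 - 1)), int(stride),
        check_bookkeeping, frames_out, energies_out, steps_out,
    )
    frames = [frame0]
    for s in range(n_got):
        chains = []
        for ci, (label, _) in enumerate(frame0.chains):
            a, b = chain_start[ci], chain_start[ci] + chain_len[ci]
            chains.append((label, frames_out[s, a:b].copy()))
        frames.append(Frame(box=frame0.box, chains=chains,
                            sequences=frame0.sequences,
                            step_index=int(steps_out[s])))
    e0 = _initial_energy(frame0, config)
    energies = np.concatenate([[e0], energies_out[:n_got]])
    steps = np.concatenate([[0], steps_out[:n_got]])
    return Trajectory(
        temperature=float(temperature),
        replicate=0,
        seed=int(seed),
        frames=frames,
        steps=steps,
        energies=energies,
        acceptance_rate=n_accept / config.total_steps if config.total_steps else 0.0,
        bookkeeping_error=float(book_err),
        analysis_fraction=config.analysis_fraction,
    )


def _initial_energy(frame: Frame, config: RunConfig) -> float:
    table = {sp.name: sp.ncpr for sp in config.species}
    return system_energy(frame, table, config.model)


def run_mc(config: RunConfig, check_bookkeeping: bool = False) -> list[Trajectory]:
    """Run the full campaign: every temperature x replicate, distinct seeds."""
    out = []
    for ti, T in enumerate(config.temperatures):
        for r in range(config.n_replicates):
            seed = config.replicate_seed(ti, r)
            traj = run_single(config, T, seed, check_bookkeeping=check_bookkeeping)
            traj.replicate = r
            out.append(traj)
    return out


# ---------------------------------------------------------------------------
# Contact counting (shared by tests and the crosslink statistic)
# ---------------------------------------------------------------------------


def contact_matrix(frame: Frame, model: InteractionModel,
                   species_order: list[str] | None = None,
                   include_intra: bool = True):
    """Count nonbonded bead-bead contacts keyed by unordered species pair.

    Returns ``(names, counts)`` with counts[i, j] == counts[j, i].
    """
    box = np.asarray(frame.box, dtype=np.int64)
    if species_order is None:
        seen = []
        for label, _ in frame.chains:
            if label not in seen:
                seen.append(label)
        species_order = seen
    sp_idx = {s: i for i, s in enumerate(species_order)}
    counts = np.zeros((len(species_order), len(species_order)))
    occupied = {}
    for ci, (label, coords) in enumerate(frame.chains):
        for bi, xyz in enumerate(np.asarray(coords) % box):
            occupied[tuple(int(v) for v in xyz)] = (ci, bi)
    offs = shell_offsets(model.neighbor_shell)
    for ci, (label, coords) in enumerate(frame.chains):
        coords = np.asarray(coords) % box
        for bi in range(len(coords)):
            for off in offs:
                key = tuple(int(v) for v in (coords[bi] + off) % box)
                hit = occupied.get(key)
                if hit is None:
                    continue
                cj, bj = hit
                if (cj, bj) <= (ci, bi):
                    continue
                if cj == ci:
                    if not include_intra:
                        continue
                    if model.bonded_excluded and abs(bj - bi) == 1:
                        continue
                si = sp_idx[label]
                sj = sp_idx[frame.chains[cj][0]]
                counts[si, sj] += 1
                if si != sj:
                    counts[sj, si] += 1
    return species_order, counts


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------


def _enumerate_saws(length: int, box: tuple, offs: np.ndarray,
                    anchored: bool) -> list[np.ndarray]:
    """All self-avoiding walks of a given length; anchored ones start at 0."""
    Lx, Ly, Lz = box
    starts = (
        [(0, 0, 0)] if anchored
        else [(x, y, z) for x in range(Lx) for y in range(Ly) for z in range(Lz)]
    )
    out = []

    def grow(walk):
        if len(walk) == length:
            out.append(np.array(walk, dtype=np.int64))
            return
        x, y, z = walk[-1]
        for o in offs:
            nxt = ((x + o[0]) % Lx, (y + o[1]) % Ly, (z + o[2]) % Lz)
            if nxt not in walk:
                # periodic self-avoidance: same site reached via another image
                grow(walk + [nxt])

    for s in starts:
        grow([s])
    return out


@njit(cache=True)
def _conf_stats(pos, box, offsets, types, e_contact, bonded_excluded):
    """Intra-conformation nonbonded contact count and energy."""
    n = pos.shape[0]
    cnt = 0
    E = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if bonded_excluded and j == i + 1:
                continue
            if _adjacent(pos[i, 0], pos[i, 1], pos[i, 2],
                         pos[j, 0], pos[j, 1], pos[j, 2],
                         box[0], box[1], box[2]):
                cnt += 1
                E += e_contact[types[i], types[j]]
    return cnt, E


@njit(cache=True)
def _cross_stats(pa, pb, box, ta, tb, e_contact):
    """Overlap flag, contact count and energy between two conformations."""
    na, nb = pa.shape[0], pb.shape[0]
    cnt = 0
    E = 0.0
    for i in range(na):
        for j in range(nb):
            dx = abs(pa[i, 0] - pb[j, 0])
            if dx > box[0] - dx:
                dx = box[0] - dx
            dy = abs(pa[i, 1] - pb[j, 1])
            if dy > box[1] - dy:
                dy = box[1] - dy
            dz = abs(pa[i, 2] - pb[j, 2])
            if dz > box[2] - dz:
                dz = box[2] - dz
            m = max(dx, max(dy, dz))
            if m == 0:
                return -1, 0.0  # overlap
            if m == 1:
                cnt += 1
                E += e_contact[ta[i], tb[j]]
    return cnt, E


@njit(cache=True)
def _enum_two(posA, posB, intraA, intraB, eintraA, eintraB, box, tA, tB,
              e_contact, elecAB, elecAA, elecBB, sA, sB, T):
    Z = 0.0
    Esum = 0.0
    c = np.zeros((3, 3))  # up to 3 species slots; indexed by species ids
    for ia in range(posA.shape[0]):
        for ib in range(posB.shape[0]):
            cross, Ec = _cross_stats(posA[ia], posB[ib], box, tA, tB, e_contact)
            if cross < 0:
                continue
            E = eintraA[ia] + eintraB[ib] + Ec + cross * elecAB \
                + intraA[ia] * elecAA + intraB[ib] * elecBB
            w = np.exp(-E / T)
            Z += w
            Esum += w * E
            c[sA, sA] += w * intraA[ia]
            c[sB, sB] += w * intraB[ib]
            if sA == sB:
                c[sA, sB] += w * cross
            else:
                c[sA, sB] += w * cross
                c[sB, sA] += w * cross
    return Z, Esum, c


def enumerate_exact(config: RunConfig, temperature: float,
                    max_states: float = 3e7):
    """Exact canonical averages of a tiny system by exhaustive enumeration.

    Supports 1-3 chains of length <= ~4 in boxes <= ~5^3.  The first chain is
    anchored at the origin (translational symmetry factored out).  Returns a
    dict with ``mean_energy`` and ``contacts`` — a (species x species)
    matrix of mean nonbonded contact counts (intra- plus inter-chain),
    matching :func:`contact_matrix` conventions.
    """
    chains = []
    for sp in config.species:
        chains.extend([sp] * sp.n_chains)
    if not 1 <= len(chains) <= 3:
        raise EnumerationTooLarge("enumeration supports 1-3 chains")
    model = config.model
    offs = shell_offsets(model.neighbor_shell)
    box = config.box
    sp_names = [sp.name for sp in config.species]
    sp_idx = {n: i for i, n in enumerate(sp_names)}
    ncprs = np.array([sp.ncpr for sp in config.species])
    elec = model.w_el * (0.5 * (ncprs[:, None] + ncprs[None, :])) ** 2

    conf_sets = []
    for k, sp in enumerate(chains):
        confs = _enumerate_saws(sp.n_residues, box, offs, anchored=(k == 0))
        conf_sets.append(confs)
    n_states = float(np.prod([len(c) for c in conf_sets]))
    if n_states > max_states:
        raise EnumerationTooLarge(
            f"state space {n_states:.2g} exceeds limit {max_states:.2g}"
        )

    boxa = np.array(box, dtype=np.int64)
    types = []
    intra = []
    eintra = []
    for k, sp in enumerate(chains):
        t = np.array([model.type_index(b) for b in sp.beads], dtype=np.int64)
        types.append(t)
        cnts = np.empty(len(conf_sets[k]), dtype=np.int64)
        es = np.empty(len(conf_sets[k]))
        for i, pos in enumerate(conf_sets[k]):
            cnts[i], es[i] = _conf_stats(pos, boxa, offs, t,
                                         model.contact_energy,
                                         model.bonded_excluded)
        intra.append(cnts)
        eintra.append(es)
    pos_arrays = [np.stack(c) for c in conf_sets]
    n_sp = len(sp_names)
    result_c = np.zeros((n_sp, n_sp))

    if len(chains) == 1:
        s0 = sp_idx[chains[0].name]
        E = eintra[0] + intra[0] * elec[s0, s0]
        w = np.exp(-E / temperature)
        Z = w.sum()
        mean_E = float((w * E).sum() / Z)
        result_c[s0, s0] = float((w * intra[0]).sum() / Z)
        return {"mean_energy": mean_E, "contacts": result_c,
                "species": sp_names, "n_states": int(len(conf_sets[0]))}

    if len(chains) == 2:
        sA, sB = sp_idx[chains[0].name], sp_idx[chains[1].name]
        Z, Esum, c = _enum_two(
            pos_arrays[0], pos_arrays[1], intra[0], intra[1],
            eintra[0], eintra[1], boxa, types[0], types[1],
            model.contact_energy, elec[sA, sB], elec[sA, sA], elec[sB, sB],
            sA, sB, temperature,
        )
        if Z == 0:
            raise RuntimeError("no feasible states")
        result_c[:] = c[:n_sp, :n_sp] / Z
        return {"mean_energy": float(Esum / Z), "contacts": result_c,
                "species": sp_names, "n_states": int(n_states)}

    # three chains: plain Python triple loop over jit-assisted pair stats
    sids = [sp_idx[sp.name] for sp in chains]
    Z = 0.0
    Esum = 0.0
    csum = np.zeros((n_sp, n_sp))
    for i0, p0 in enumerate(pos_arrays[0]):
        for i1, p1 in enumerate(pos_arrays[1]):
            c01, E01 = _cross_stats(p0, p1, boxa, types[0], types[1],
                                    model.contact_energy)
            if c01 < 0:
                continue
            for i2, p2 in enumerate(pos_arrays[2]):
                c02, E02 = _cross_stats(p0, p2, boxa, types[0], types[2],
                                        model.contact_energy)
                if c02 < 0:
                    continue
                c12, E12 = _cross_stats(p1, p2, boxa, types[1], types[2],
                                        model.contact_energy)
                if c12 < 0:
                    continue
                E = (eintra[0][i0] + eintra[1][i1] + eintra[2][i2]
                     + E01 + E02 + E12
                     + intra[0][i0] * elec[sids[0], sids[0]]
                     + intra[1][i1] * elec[sids[1], sids[1]]
                     + intra[2][i2] * elec[sids[2], sids[2]]
                     + c01 * elec[sids[0], sids[1]]
                     + c02 * elec[sids[0], sids[2]]
                     + c12 * elec[sids[1], sids[2]])
                w = np.exp(-E / temperature)
                Z += w
                Esum += w * E
                for (a, b, cc) in ((0, 1, c01), (0, 2, c02), (1, 2, c12)):
                    csum[sids[a], sids[b]] += w * cc
                    if sids[a] != sids[b]:
                        csum[sids[b], sids[a]] += w * cc
                for a in range(3):
                    csum[sids[a], sids[a]] += w * intra[a][[i0, i1, i2][a]]
    if Z == 0:
        raise RuntimeError("no feasible states")
    return {"mean_energy": float(Esum / Z), "contacts": csum / Z,
            "species": sp_names, "n_states": int(n_states)}


# ---------------------------------------------------------------------------
# Equilibration advisory and I/O
# ---------------------------------------------------------------------------


def energy_plateau_step(steps: np.ndarray, energies: np.ndarray,
                        window: int = 10, slope_tol: float = 1.0) -> int | None:
    """First sampled step after which the energy trace is plateaued.

    Advisory only: a sliding window is called flat when the magnitude of its
    fitted slope drops below ``slope_tol`` standard errors.  Returns None if
    no plateau is found.
    """
    steps = np.asarray(steps, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if len(steps) < window + 1:
        return None
    for i in range(len(steps) - window):
        x = steps[i : i + window]
        y = energies[i : i + window]
        x0 = x - x.mean()
        denom = (x0**2).sum()
        if denom == 0:
            continue
        slope = (x0 * y).sum() / denom
        resid = y - y.mean() - slope * x0
        dof = window - 2
        se = np.sqrt((resid**2).sum() / dof / denom) if dof > 0 else np.inf
        if se == 0 or abs(slope) < slope_tol * se:
            return int(steps[i])
    return None


def write_energy_trace(traj: Trajectory, path) -> None:
    """Energy trace as TSV: step <tab> energy."""
    with open(path, "w") as fh:
        fh.write("step\tenergy\n")
        for s, e in zip(traj.steps, traj.energies):
            fh.write(f"{int(s)}\t{e:.10g}\n")


def write_trajectory_text(traj: Trajectory, path) -> None:
    """Plain-text trajectory: per frame a header line then per-chain lines.

    Layout::

        #traj temperature=<T> seed=<seed> box=<Lx,Ly,Lz>
        #frame step=<n> energy=<E>
        <species label> <x0,y0,z0> <x1,y1,z1> ...
    """
    with open(path, "w") as fh:
        f0 = traj.frames[0]
        fh.write(
            f"#traj temperature={traj.temperature} seed={traj.seed} "
            f"box={f0.box[0]},{f0.box[1]},{f0.box[2]}\n"
        )
        for frame, step, e in zip(traj.frames, traj.steps, traj.energies):
            fh.write(f"#frame step={int(step)} energy={e:.10g}\n")
            for label, coords in frame.chains:
                cells = " ".join(",".join(str(int(v)) for v in p) for p in coords)
                fh.write(f"{label} {cells}\n")


def read_trajectory_text(path, sequences: dict) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory_text`."""
    frames = []
    steps = []
    energies = []
    T = 0.0
    seed = 0
    box = (0, 0, 0)
    chains = None
    step = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#traj"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                T = float(fields["temperature"])
                seed = int(fields["seed"])
                box = tuple(int(v) for v in fields["box"].split(","))
            elif line.startswith("#frame"):
                if chains is not None:
                    frames.append(Frame(box=box, chains=chains,
                                        sequences=sequences, step_index=step))
                fields = dict(kv.split("=") for kv in line.split()[1:])
                step = int(fields["step"])
                steps.append(step)
                energies.append(float(fields["energy"]))
                chains = []
            else:
                label, *cells = line.split()
                coords = np.array(
                    [[int(v) for v in c.split(",")] for c in cells], dtype=np.int64
                )
                chains.append((label, coords))
    if chains is not None:
        frames.append(Frame(box=box, chains=chains, sequences=sequences,
                            step_index=step))
    return Trajectory(
        temperature=T, replicate=0, seed=seed, frames=frames,
        steps=np.array(steps), energies=np.array(energies),
        acceptance_rate=float("nan"), bookkeeping_error=float("nan"),
    )
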