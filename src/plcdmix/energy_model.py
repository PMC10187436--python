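"""Bead-bead interaction energies: contact matrix + mean-field electrostatics.

A contact is a pair of beads occupying sites within the neighbor shell of a
cubic lattice (26 sites by default, chain-bonded pairs excluded).  Its energy
is the symmetric bead-type contact energy plus an electrostatic modifier
computed from the net charge per residue (NCPR) of the two *chains* the beads
belong to:

    E(i, j) = e_contact[type_i, type_j] + w_el * m_bar**2,
    m_bar   = (NCPR_chain_a + NCPR_chain_b) / 2.

The quadratic form is this package's choice of modifier: it is even, vanishes
when the two chains' charges are complementary (m_bar = 0), and penalises
like-charged pairs — which is what lets oppositely charged species co-phase
separate more readily than either alone (complex coacervation), while a
mixture of two like-charged species is penalised.  Energies are in reduced
units with k_B = 1; negative values are attractive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "InteractionModel",
    "UnknownBeadTypeError",
    "pair_energy",
    "build_scenario_matrix",
    "system_energy",
    "default_plcd_model",
    "read_contact_table",
    "write_contact_table",
    "SCENARIOS",
    "shell_offsets",
]

SCENARIOS = ("equal", "hetero_stronger", "homo_stronger", "asymmetric_A_weak")


class UnknownBeadTypeError(KeyError):
    """Raised when a bead type is absent from the interaction matrix."""


def shell_offsets(neighbor_shell: int = 26) -> np.ndarray:
    """Integer offsets of the contact shell (26 = full cube, 6 = faces)."""
    if neighbor_shell == 26:
        offs = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    elif neighbor_shell == 6:
        offs = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ]
    else:
        raise ValueError("neighbor_shell must be 6 or 26")
    return np.array(offs, dtype=np.int64)


@dataclass(frozen=True)
class InteractionModel:
    """Symmetric bead-type contact energies plus an electrostatic coupling.

    ``contact_energy`` is indexed by the position of each code in
    ``bead_types``; ``w_el >= 0`` scales the quadratic NCPR penalty.
    """

    bead_types: tuple[str, ...]
    contact_energy: np.ndarray
    w_el: float = 0.0
    neighbor_shell: int = 26
    bonded_excluded: bool = True

    def __post_init__(self) -> None:
        e = np.asarray(self.contact_energy, dtype=float)
        if e.shape != (len(self.bead_types), len(self.bead_types)):
            raise ValueError("contact_energy shape does not match bead_types")
        if not np.allclose(e, e.T, atol=1e-12):
            raise ValueError("contact_energy must be symmetric")
        if self.w_el < 0:
            raise ValueError("w_el must be non-negative")
        if self.neighbor_shell not in (6, 26):
            raise ValueError("neighbor_shell must be 6 or 26")
        object.__setattr__(self, "contact_energy", e)

    def type_index(self, code: str) -> int:
        try:
            return self.bead_types.index(code)
        except ValueError:
            raise UnknownBeadTypeError(
                f"bead type {code!r} not in model (have {self.bead_types})"
            ) from None

    def offsets(self) -> np.ndarray:
        return shell_offsets(self.neighbor_shell)


def pair_energy(
    type_i: str,
    type_j: str,
    ncpr_chain_a: float,
    ncpr_chain_b: float,
    model: InteractionModel,
) -> float:
    """Energy of one bead-bead contact, including the electrostatic modifier."""
    for v in (ncpr_chain_a, ncpr_chain_b):
        if not -1.0 <= v <= 1.0:
            raise ValueError("chain NCPR must lie in [-1, 1]")
    base = model.contact_energy[model.type_index(type_i), model.type_index(type_j)]
    m_bar = 0.5 * (ncpr_chain_a + ncpr_chain_b)
    return float(base + model.w_el * m_bar * m_bar)


def build_scenario_matrix(
    scenario: str,
    e_base: float = -1.0,
    delta: float = 0.5,
    bead_types: tuple[str, str] = ("A", "B"),
    w_el: float = 0.0,
) -> InteractionModel:
    """Two-species interaction matrices for the four canonical scenarios.

    equal
        All homotypic and heterotypic energies identical (random mixing null).
    hetero_stronger
        A-B stronger than A-A = B-B (maximised heterotypic contacts).
    homo_stronger
        A-A = B-B stronger than A-B (internally demixed condensate).
    asymmetric_A_weak
        A-A weaker than A-B = B-B (A prefers B; B indifferent at low T).
    """
    if e_base >= 0:
        raise ValueError("e_base must be negative (attractive)")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    e = np.full((2, 2), e_base, dtype=float)
    if scenario == "equal":
        pass
    elif scenario == "hetero_stronger":
        e[0, 1] = e[1, 0] = e_base - delta
    elif scenario == "homo_stronger":
        e[0, 0] = e[1, 1] = e_base - delta
    elif scenario == "asymmetric_A_weak":
        e[0, 0] = e_base + delta
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    return InteractionModel(bead_types=tuple(bead_types), contact_energy=e, w_el=w_el)


def system_energy(frame, species_table, model: InteractionModel) -> float:
    """Total contact energy of a frame (reference implementation).

    Sums ``pair_energy`` over all unordered bead pairs on shell-adjacent
    sites, excluding chain-bonded neighbors when the model says so.  This is
    the slow, transparent bookkeeping oracle; the Monte Carlo engine tracks
    the same quantity incrementally.

    ``species_table`` maps species label -> NCPR (float) or an object with an
    ``ncpr`` attribute.
    """
    box = np.asarray(frame.box, dtype=np.int64)
    if np.any(box < 3):
        raise ValueError("box must be at least 3 per axis")
    occupied: dict[tuple[int, int, int], tuple[int, int]] = {}
    for ci, (label, coords) in enumerate(frame.chains):
        for bi, xyz in enumerate(np.asarray(coords) % box):
            key = tuple(int(v) for v in xyz)
            if key in occupied:
                raise ValueError(f"overlapping beads at site {key}")
            occupied[key] = (ci, bi)

    def _ncpr(entry):
        return entry if isinstance(entry, (int, float)) else entry.ncpr

    offs = model.offsets()
    total = 0.0
    for ci, (label, coords) in enumerate(frame.chains):
        coords = np.asarray(coords) % box
        for bi in range(len(coords)):
            here = coords[bi]
            for off in offs:
                key = tuple(int(v) for v in (here + off) % box)
                hit = occupied.get(key)
                if hit is None:
                    continue
                cj, bj = hit
                if (cj, bj) <= (ci, bi):
                    continue  # count each unordered pair once
                if (
                    model.bonded_excluded
                    and cj == ci
                    and abs(bj - bi) == 1
                ):
                    continue
                label_j, coords_j = frame.chains[cj]
                ti = frame.bead_type(ci, bi)
                tj = frame.bead_type(cj, bj)
                total += pair_energy(
                    ti, tj,
                    _ncpr(species_table[label]),
                    _ncpr(species_table[label_j]),
                    model,
                )
    return total


# ---------------------------------------------------------------------------
# Residue-level default matrix (stickers and spacers)
# ---------------------------------------------------------------------------

_AA = tuple("ACDEFGHIKLMNPQRSTVWY")
_STICKERS = frozenset("FYW")  # aromatic stickers
_AROMATIC_AUX = frozenset("H")
_CHARGED = frozenset("DERK")


def default_plcd_model(w_el: float = 0.0) -> InteractionModel:
    """Default residue-level stickers-and-spacers contact matrix.

    A deliberately simple hierarchy, not a fitted parameter set: aromatic
    sticker pairs (F/Y/W) are strongly attractive, sticker-Arg pairs carry an
    auxiliary attraction (cation-pi), His is a half-strength sticker, and all
    remaining (spacer) pairs share a weak background attraction.  Users
    fitting real systems should supply their own table via
    ``read_contact_table``.
    """
    e = np.full((20, 20), -0.20)  # spacer background
    idx = {a: i for i, a in enumerate(_AA)}

    def set_pair(a, b, val):
        e[idx[a], idx[b]] = e[idx[b], idx[a]] = val

    for a in _STICKERS:
        for b in _STICKERS:
            set_pair(a, b, -2.0)
        set_pair(a, "H", -1.0)
        set_pair(a, "R", -0.8)  # cation-pi auxiliary
    set_pair("H", "H", -0.5)
    return InteractionModel(bead_types=_AA, contact_energy=e, w_el=w_el)


def write_contact_table(model: InteractionModel, path) -> None:
    """Write the contact matrix as a plain-text symmetric table."""
    with open(path, "w") as fh:
        fh.write("\t".join(("type", *model.bead_types)) + "\n")
        for i, t in enumerate(model.bead_types):
            row = "\t".join(f"{v:.6g}" for v in model.contact_energy[i])
            fh.write(f"{t}\t{row}\n")


def read_contact_table(path, w_el: float = 0.0, neighbor_shell: int = 26) -> InteractionModel:
    """Read a contact matrix written by :func:`write_contact_table`."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        rows.append([float(v) for v in parts[1:]])
    return InteractionModel(
        bead_types=tuple(header),
        contact_energy=np.array(rows),
        w_el=w_el,
        neighbor_shell=neighbor_shell,
    )
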