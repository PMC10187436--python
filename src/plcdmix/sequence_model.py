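"""Polymer species and sequence-composition descriptors.

A species is a chain type on the lattice: one bead per residue, either a
real amino-acid sequence (prion-like low-complexity domains, PLCDs) or a
generic homopolymer bead type ("A", "B", ...).  The descriptors computed
here — net charge per residue (NCPR), fraction of charged residues (FCR)
and the five-category composition profile (polar / aromatic / hydrophobic /
charged / other) — feed the electrostatic term of the energy model and the
compositional profiling of PLCD sequences.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "PolymerSpecies",
    "CompositionProfile",
    "UnknownResidueError",
    "classify_residue",
    "composition_profile",
    "ncpr",
    "fcr",
    "read_fasta_species",
]

# Category membership for the 20 canonical residues.  His is aromatic but
# counted neutral for charge; Pro and Ala fall in "other" together with
# anything not claimed by the four named categories.
_POLAR = frozenset("GSTNQC")
_AROMATIC = frozenset("FYWH")
_HYDROPHOBIC = frozenset("LIVM")
_CHARGED = frozenset("DERK")
_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")
_CANONICAL = frozenset("ACDEFGHIKLMNPQRSTVWY")

CATEGORIES = ("polar", "aromatic", "hydrophobic", "charged", "other")


class UnknownResidueError(ValueError):
    """Raised when a residue code is not one of the 20 canonical letters."""


def classify_residue(aa: str) -> str:
    """Assign a one-letter residue code to a composition category.

    Polar: G, S, T, N, Q, C.  Aromatic: F, Y, W, H.  Hydrophobic:
    L, I, V, M.  Charged: D, E, R, K.  Everything else (P, A) is "other".
    """
    code = aa.upper()
    if code not in _CANONICAL:
        raise UnknownResidueError(f"not a canonical residue code: {aa!r}")
    if code in _POLAR:
        return "polar"
    if code in _AROMATIC:
        return "aromatic"
    if code in _HYDROPHOBIC:
        return "hydrophobic"
    if code in _CHARGED:
        return "charged"
    return "other"


def _charge_counts(beads: Iterable[str]) -> tuple[int, int]:
    pos = neg = 0
    for b in beads:
        if b in _POSITIVE:
            pos += 1
        elif b in _NEGATIVE:
            neg += 1
    return pos, neg


@dataclass(frozen=True)
class PolymerSpecies:
    """A named chain type: bead sequence, chain count and charge descriptors.

    Parameters
    ----------
    name
        Species label, unique within a system.
    beads
        Ordered bead-type codes.  Amino-acid species use one-letter residue
        codes; homopolymers use a single generic type per chain.
    n_chains
        Number of chains of this species in the simulated system.
    ncpr_override
        Net charge per residue to use instead of the sequence-derived value.
        Generic bead types carry NCPR 0 unless this is set, so that pure
        contact-matrix scenarios have inert electrostatics.
    """

    name: str
    beads: tuple[str, ...]
    n_chains: int = 0
    ncpr_override: float | None = None
    is_amino_acid: bool = True

    def __post_init__(self) -> None:
        if len(self.beads) < 2:
            raise ValueError(f"species {self.name!r}: need at least 2 beads")
        if self.n_chains < 0:
            raise ValueError("n_chains must be non-negative")
        if self.is_amino_acid:
            bad = {b for b in self.beads if b not in _CANONICAL}
            if bad:
                raise UnknownResidueError(
                    f"species {self.name!r}: non-canonical residues {sorted(bad)}"
                )
        if self.ncpr_override is not None and not -1.0 <= self.ncpr_override <= 1.0:
            raise ValueError("ncpr_override must lie in [-1, 1]")

    @classmethod
    def from_sequence(
        cls, name: str, sequence: str, n_chains: int = 0
    ) -> "PolymerSpecies":
        """Build an amino-acid species from a plain string (case-insensitive)."""
        seq = "".join(sequence.split()).upper()
        return cls(name=name, beads=tuple(seq), n_chains=n_chains)

    @classmethod
    def homopolymer(
        cls,
        name: str,
        bead_type: str,
        length: int,
        n_chains: int = 0,
        ncpr: float = 0.0,
    ) -> "PolymerSpecies":
        """Build a generic homopolymer species of a single bead type."""
        return cls(
            name=name,
            beads=(bead_type,) * length,
            n_chains=n_chains,
            ncpr_override=ncpr,
            is_amino_acid=False,
        )

    @property
    def n_residues(self) -> int:
        return len(self.beads)

    @property
    def sequence(self) -> str:
        return "".join(self.beads)

    @property
    def is_homopolymer(self) -> bool:
        return len(set(self.beads)) == 1

    @property
    def ncpr(self) -> float:
        if self.ncpr_override is not None:
            return self.ncpr_override
        pos, neg = _charge_counts(self.beads)
        return (pos - neg) / self.n_residues

    @property
    def fcr(self) -> float:
        if not self.is_amino_acid:
            return abs(self.ncpr)
        pos, neg = _charge_counts(self.beads)
        return (pos + neg) / self.n_residues


@dataclass(frozen=True)
class CompositionProfile:
    """Category and per-residue fractions of a sequence; both sum to 1."""

    category_fractions: Mapping[str, float]
    residue_fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, frac in (
            ("category", self.category_fractions),
            ("residue", self.residue_fractions),
        ):
            total = sum(frac.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{label} fractions sum to {total}, not 1")


def composition_profile(species: PolymerSpecies) -> CompositionProfile:
    """Category and residue fractions of an amino-acid species."""
    if not species.is_amino_acid:
        raise ValueError("composition profiles are defined for amino-acid species")
    n = species.n_residues
    cats = dict.fromkeys(CATEGORIES, 0)
    res: dict[str, int] = {}
    for b in species.beads:
        cats[classify_residue(b)] += 1
        res[b] = res.get(b, 0) + 1
    return CompositionProfile(
        category_fractions={k: v / n for k, v in cats.items()},
        residue_fractions={k: v / n for k, v in sorted(res.items())},
    )


def ncpr(species: PolymerSpecies) -> float:
    """Net charge per residue: (K + R − D − E) / N.  His counts neutral."""
    return species.ncpr


def fcr(species: PolymerSpecies) -> float:
    """Fraction of charged residues: (K + R + D + E) / N."""
    return species.fcr


def read_fasta_species(source, n_chains: int = 0) -> list[PolymerSpecies]:
    """Read species from FASTA (path, file object, or string content).

    Each record becomes one amino-acid species named by the record id.
    """
    from Bio import SeqIO

    if isinstance(source, str) and source.lstrip().startswith(">"):
        handle = io.StringIO(source)
    else:
        handle = source
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    return [
        PolymerSpecies.from_sequence(rec.id, str(rec.seq), n_chains=n_chains)
        for rec in records
    ]
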