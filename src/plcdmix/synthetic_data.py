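"""Generators for every input the pipeline needs, with no downloads.

Four families:

* the canonical two-species homopolymer scenarios (equal / heterotypic-
  stronger / homotypic-stronger / asymmetric interaction matrices; and the
  length scenarios 150+300, matched-c_sat 150+300, and 200+300+400), at
  "full" (production), "desk" or "mini" problem sizes;
* enumerable toy systems small enough for exact Boltzmann enumeration;
* random PLCD-like sequences matching a target category composition, with
  aromatic stickers placed near-uniformly along the chain;
* the packaged study sequences (A1-LCD, A1-LCD+12D, FUS-LCD), checksummed.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .energy_model import (
    InteractionModel,
    build_scenario_matrix,
    default_plcd_model,
)
from .lattice_engine import RunConfig
from .sequence_model import PolymerSpecies, classify_residue, read_fasta_species

__all__ = [
    "ScenarioSpec",
    "SCENARIO_IDS",
    "make_homopolymer_system",
    "make_enumerable_toy",
    "make_random_plcd",
    "study_fixture",
    "DEFAULT_PLCD_TARGETS",
]

SCENARIO_IDS = (
    "mix_equal",        # all homotypic and heterotypic energies equal
    "mix_hetero",       # heterotypic stronger: maximally mixed condensate
    "mix_homo",         # homotypic stronger: internally demixed condensate
    "mix_asym",         # A-A weakened: A prefers B
    "length_mixture",   # H150 + H300, equal energies, equal mass
    "length_matched",   # H150 + H300 with H300's energies scaled to match c_sat
    "three_lengths",    # H200 + H300 + H400, equal energies, equal mass
    "toy_enumerable",   # tiny system for the exact-enumeration oracle
    "plcd_mixture",     # A1-LCD + FUS-LCD with the default residue matrix
)

_SCENARIO_TO_MATRIX = {
    "mix_equal": "equal",
    "mix_hetero": "hetero_stronger",
    "mix_homo": "homo_stronger",
    "mix_asym": "asymmetric_A_weak",
}

# Desk-size presets.  Chain lengths are never shrunk for the length
# scenarios (length is the variable under study); the interaction-matrix
# battery additionally offers a "mini" 75-bead variant because its claims
# are length-independent.  The target bead volume fraction is 0.016
# throughout, matching the dense-seed initialization protocol.
_FULL_STEPS = 30_000_000_000
_SIZES = {
    # scenario family -> scale -> (chain lengths, box, init_box, steps)
    "mix": {
        "full": ((150, 150), 150, 35, _FULL_STEPS),
        "desk": ((150, 150), 64, 24, 40_000_000),
        "mini": ((75, 75), 48, 18, 12_000_000),
    },
    "length_mixture": {
        "full": ((150, 300), 150, 35, _FULL_STEPS),
        "desk": ((150, 300), 64, 26, 40_000_000),
        "mini": ((150, 300), 52, 24, 20_000_000),
    },
    "three_lengths": {
        "full": ((200, 300, 400), 150, 35, _FULL_STEPS),
        "desk": ((200, 300, 400), 64, 28, 40_000_000),
        "mini": ((200, 300, 400), 52, 26, 20_000_000),
    },
}

# Reduced-unit temperature presets inside the two-phase window of the
# e_base = -1 default matrix at these sizes (see docs/methods.md).
_TEMPS = {
    "mix": (12.0, 13.0, 14.0),
    "length_mixture": (14.0, 15.0, 16.0),
    "three_lengths": (14.0, 15.0, 16.0),
}

DEFAULT_PLCD_TARGETS = {
    # average PLCD composition: mostly polar spacers, ~10% aromatic
    # stickers, few charges, the rest Pro/Ala ("other") and aliphatics
    "polar": 0.55,
    "aromatic": 0.10,
    "hydrophobic": 0.14,
    "charged": 0.05,
    "other": 0.16,
}

_CATEGORY_RESIDUES = {
    "polar": "GSTNQ",
    "aromatic": "YF",
    "hydrophobic": "LIVM",
    "charged": "DEKR",
    "other": "PA",
}

_FIXTURE_FILE = "study_plcds.synthetic.fasta"
_FIXTURE_SHA256 = "f2c972fa940e9675385a649221f9a865a1f3930cb4c70cd78c034b253af39e50"


@dataclass(frozen=True)
class ScenarioSpec:
    """A named study condition at a given problem size."""

    scenario: str
    scale: str = "desk"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_IDS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIO_IDS}"
            )
        if self.scale not in ("full", "desk", "mini"):
            raise ValueError("scale must be full, desk or mini")


def _chain_counts(lengths, box: int, phi: float = 0.016):
    """Equal-mass mixing: the same total bead count per species."""
    v = box**3
    per_species = phi * v / len(lengths)
    counts = [max(2, round(per_species / n)) for n in lengths]
    return counts


def make_homopolymer_system(
    spec: ScenarioSpec | str,
    scale: str = "desk",
    seed: int = 0,
    e_base: float = -1.0,
    delta: float = 0.3,
    matched_scale: float = 1.0,
    temperatures=None,
    n_replicates: int = 5,
    total_steps: int | None = None,
    **config_kwargs,
) -> RunConfig:
    """Build the run configuration for a homopolymer scenario.

    Chain counts hit the target volume fraction 0.016 with equal total bead
    counts per species (equal-mass mixing).  ``matched_scale`` multiplies
    the second species' homotypic and heterotypic energies in the
    ``length_matched`` scenario (tune it with
    :func:`plcdmix.mixture_analysis.match_csat`).
    """
    if isinstance(spec, str):
        spec = ScenarioSpec(spec, scale=scale, seed=seed)
    sc = spec.scenario
    if sc == "toy_enumerable":
        return make_enumerable_toy(2, 2, 4, {("A", "B"): -1.0}, seed=spec.seed)
    if sc == "plcd_mixture":
        return _make_plcd_mixture(spec, temperatures=temperatures,
                                  n_replicates=n_replicates,
                                  total_steps=total_steps, **config_kwargs)
    if sc in _SCENARIO_TO_MATRIX:
        family = "mix"
    elif sc == "length_matched":
        family = "length_mixture"
    else:
        family = sc
    lengths, box, init_box, steps = _SIZES[family][spec.scale]
    if total_steps is not None:
        steps = total_steps
    box = config_kwargs.pop("box", box)
    if not np.isscalar(box):
        box = box[0]
    init_box = config_kwargs.pop("init_box", init_box)
    counts = _chain_counts(lengths, box)
    names = [f"H{n}" if len(set(lengths)) > 1 else ("A", "B", "C")[i]
             for i, n in enumerate(lengths)]
    species = [
        PolymerSpecies.homopolymer(name, ("A", "B", "C")[i], n, counts[i])
        for i, (name, n) in enumerate(zip(names, lengths))
    ]
    if sc in _SCENARIO_TO_MATRIX:
        model = build_scenario_matrix(_SCENARIO_TO_MATRIX[sc], e_base, delta)
    else:
        n_sp = len(lengths)
        e = np.full((n_sp, n_sp), e_base)
        if sc == "length_matched":
            # scale species 2's homotypic and heterotypic attractions
            e[1, :] *= matched_scale
            e[:, 1] *= matched_scale
            e[1, 1] = e_base * matched_scale  # not scaled twice
        model = InteractionModel(
            bead_types=tuple("ABC"[:n_sp]), contact_energy=e
        )
    temps = tuple(temperatures) if temperatures is not None else _TEMPS[family]
    return RunConfig(
        species=species,
        model=model,
        box=box,
        init_box=init_box,
        temperatures=temps,
        total_steps=steps,
        n_replicates=n_replicates,
        seed=spec.seed,
        **config_kwargs,
    )


def _make_plcd_mixture(spec: ScenarioSpec, fraction_a1: float = 0.5,
                       w_el: float = 2.0, temperatures=None,
                       n_replicates: int = 5, total_steps: int | None = None,
                       **config_kwargs) -> RunConfig:
    sizes = {"full": (120, 35, _FULL_STEPS), "desk": (56, 26, 40_000_000),
             "mini": (48, 24, 20_000_000)}
    box, init_box, steps = sizes[spec.scale]
    if total_steps is not None:
        steps = total_steps
    box = config_kwargs.pop("box", box)
    init_box = config_kwargs.pop("init_box", init_box)
    a1 = study_fixture("A1_LCD")
    fus = study_fixture("FUS_LCD")
    total_beads = 0.016 * box**3
    n_a1 = max(1, round(fraction_a1 * total_beads / a1.n_residues))
    n_fus = max(1, round((1 - fraction_a1) * total_beads / fus.n_residues))
    species = [
        PolymerSpecies.from_sequence("A1_LCD", a1.sequence, n_chains=n_a1),
        PolymerSpecies.from_sequence("FUS_LCD", fus.sequence, n_chains=n_fus),
    ]
    model = default_plcd_model(w_el=w_el)
    temps = tuple(temperatures) if temperatures is not None else (3.0, 3.5)
    return RunConfig(
        species=species, model=model, box=box, init_box=init_box,
        temperatures=temps, total_steps=steps, n_replicates=n_replicates,
        seed=spec.seed, **config_kwargs,
    )


def make_enumerable_toy(n_chains: int, length: int, box: int,
                        energies, temperature: float = 1.0,
                        seed: int = 0, w_el: float = 0.0,
                        ncprs=(0.0, 0.0)) -> RunConfig:
    """A tiny two-species system within the exact-enumeration limits.

    Chains alternate between species A and B; ``energies`` is either a
    scalar (all pairs) or a mapping over ("A","A"), ("A","B"), ("B","B").
    The exact configuration count is reported by ``enumerate_exact``.
    """
    if n_chains < 1 or n_chains > 3:
        raise ValueError("enumerable toys support 1-3 chains")
    if length < 2 or length > 4:
        raise ValueError("enumerable toys support chain lengths 2-4")
    if box < 3 or box > 5:
        raise ValueError("enumerable toys support boxes 3-5 per axis")
    e = np.zeros((2, 2))
    if np.isscalar(energies):
        e[:] = energies
    else:
        for (a, b), v in energies.items():
            i, j = "AB".index(a), "AB".index(b)
            e[i, j] = e[j, i] = v
    model = InteractionModel(bead_types=("A", "B"), contact_energy=e, w_el=w_el)
    n_a = (n_chains + 1) // 2
    n_b = n_chains - n_a
    species = [PolymerSpecies.homopolymer("A", "A", length, n_a, ncpr=ncprs[0])]
    if n_b:
        species.append(
            PolymerSpecies.homopolymer("B", "B", length, n_b, ncpr=ncprs[1])
        )
    return RunConfig(
        species=species, model=model, box=box, init_box=box,
        temperatures=(temperature,), total_steps=0,
        n_replicates=1, seed=seed,
    )


def make_random_plcd(length: int, category_targets=None, seed: int = 0) -> str:
    """A random PLCD-like sequence with stickers spread near-uniformly.

    Category fractions of the result match the targets to within 1/length
    (largest-remainder allocation); aromatic positions are evenly spaced
    with seeded jitter, remaining positions are a shuffled multiset of the
    other categories.
    """
    targets = dict(DEFAULT_PLCD_TARGETS if category_targets is None
                   else category_targets)
    missing = set(targets) - set(_CATEGORY_RESIDUES)
    if missing:
        raise ValueError(f"unknown categories: {sorted(missing)}")
    total = sum(targets.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category targets sum to {total}, not 1")
    rng = np.random.default_rng(seed)
    cats = sorted(targets)
    ideal = np.array([targets[c] * length for c in cats])
    counts = np.floor(ideal).astype(int)
    rem = length - counts.sum()
    order = np.argsort(-(ideal - counts))
    for k in range(rem):
        counts[order[k % len(cats)]] += 1

    seq = [None] * length
    n_arom = counts[cats.index("aromatic")] if "aromatic" in cats else 0
    if n_arom:
        # even spacing with +-1 jitter keeps stickers near-uniform
        anchors = (np.arange(n_arom) + 0.5) * length / n_arom
        pos = np.clip(np.round(anchors + rng.integers(-1, 2, n_arom)),
                      0, length - 1).astype(int)
        while len(set(pos)) < n_arom:  # resolve collisions deterministically
            for i in range(1, n_arom):
                if pos[i] <= pos[i - 1]:
                    pos[i] = pos[i - 1] + 1
            pos = np.clip(pos, 0, length - 1)
            if pos[-1] >= length:
                pos -= pos[-1] - length + 1
        for p in pos:
            seq[p] = rng.choice(list(_CATEGORY_RESIDUES["aromatic"]))
    rest = []
    for c, n in zip(cats, counts):
        if c == "aromatic":
            continue
        pool = list(_CATEGORY_RESIDUES[c])
        rest.extend(rng.choice(pool, size=n))
    rng.shuffle(rest)
    it = iter(rest)
    for i in range(length):
        if seq[i] is None:
            seq[i] = next(it)
    out = "".join(str(s) for s in seq)
    assert len(out) == length
    return out


class FixtureChecksumError(RuntimeError):
    """The packaged sequence fixture does not match its recorded checksum."""


def study_fixture(name: str) -> PolymerSpecies:
    """One of the packaged study sequences: A1_LCD, A1_LCD_12D, FUS_LCD.

    The sequences are reconstructions from the published construct
    definitions (see the fixture file's record headers); the file's SHA-256
    is verified on every load.
    """
    ref = resources.files("plcdmix.data") / _FIXTURE_FILE
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureChecksumError(
            f"fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    species = read_fasta_species(data.decode())
    by_name = {sp.name: sp for sp in species}
    if name not in by_name:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(by_name)}")
    return by_name[name]
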