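# Methods

## The model

`plcdmix` simulates mixtures of coarse-grained polymers on a periodic cubic
lattice in the canonical ensemble. Each chain bead represents one residue
(or one generic monomer for homopolymers) and occupies one lattice site;
vacant sites are implicit solvent and carry no energy. Consecutive beads of
a chain sit within the 26-neighbor shell of each other (the "any touching
cube" bond convention); the same shell defines nonbonded contacts. The
energy of a configuration is the sum over nonbonded contact pairs of

    E(i, j) = e_contact[type_i, type_j] + w_el * m_bar^2,
    m_bar   = (NCPR_a + NCPR_b) / 2,

where `e_contact` is a symmetric bead-type contact matrix (reduced units,
negative = attractive) and the second term is a mean-field electrostatic
modifier built from the net charge per residue (NCPR) of the two *chains*
the beads belong to — not of the beads themselves. Sampling is
Metropolis Monte Carlo: a proposed move is accepted with probability
min[1, exp(-dE/T)] with k_B = 1, so temperatures are in reduced energy
units.

### Why the chain-pair-averaged quadratic electrostatic term

Averaging NCPR over the two chains makes the modifier vanish when the
partners carry complementary charge (m_bar = 0) and penalise like-charged
pairs, which is the minimal mechanism by which two oppositely charged
species co-phase-separate more readily than either alone (complex
coacervation). The quadratic form is this package's own choice: it is even,
zero at charge complementarity, and repulsive otherwise. One consequence
worth stating explicitly: because the square is a convex function, the
heterotypic penalty ((a+b)/2)^2 can never exceed the mean of the homotypic
penalties (a^2 + b^2)/2. A pairwise mean-field electrostatic term of this
kind can therefore produce positive cooperativity (a concave dilute arm)
for complementary charges, and can at best erase — not invert — that
cooperativity when both species carry like charge. Strongly convex dilute
arms in real PLCD mixtures also involve compositional and length asymmetry
between the species; the directional test shipped with the package
accordingly checks for the concave -> non-concave flip when one species'
charge sign is flipped, as a sign/ordering statement. The functional form
is pluggable through `InteractionModel`.

### The default residue matrix

`default_plcd_model()` encodes a stickers-and-spacers hierarchy — aromatic
pairs (F/Y/W) at -2.0, aromatic-His at -1.0, aromatic-Arg (cation-pi) at
-0.8, His-His at -0.5, and a -0.2 spacer background — chosen to be simple
and qualitatively ordered, not fitted to any experimental data set. Users
reproducing quantitative work must supply their own matrix
(`read_contact_table`).

## Monte Carlo moves

Seven proposal kinds are implemented: single-bead relocation within the
shell, slithering-snake reptation, rigid chain translation (per-axis shifts
in {-2..2}), pivot (one of the 48 cubic point-group operations applied to a
chain segment about a pivot bead), double pivot (inversion-plus-reversal of
an interior segment through the midpoint of its two anchor beads — an exact
lattice crankshaft), co-local translation of a bead together with one shell
partner, and rigid translation of an entire connected cluster of chains.
All proposal distributions are symmetric (each move is its own inverse or
is drawn from a group closed under inverses), so plain Metropolis acceptance
gives detailed balance. Cluster translations are accepted only when they
create no new cluster-external contacts; since a maximal cluster has none
before the move, the proposal is symmetric and energy-neutral. Infeasible
proposals (broken bonds, occupied targets) count as rejected moves.

The default move mix (50% local bead, 14% snake, 12% pivot, 10% double
pivot, 8% translation, 5% co-local, 1% cluster) weights cheap O(1) moves
heavily because chain-scale moves cost O(N) per proposal and cluster moves
O(cluster). Weights are config-overridable; the production lineage this
engine follows publishes its own move tables, which we deliberately do not
transcribe.

Energy is tracked incrementally: each proposal computes dE from the moved
beads' shell neighborhoods only. The kernel can recompute the total energy
from scratch at every sample point and report the maximum bookkeeping
discrepancy (`check_bookkeeping=True`); tests require closure at 1e-9.

## Exact enumeration oracle

For systems of 1-3 chains of length <= 4 in boxes of 3-5 sites per axis,
`enumerate_exact` computes canonical averages by exhaustive enumeration of
self-avoiding placements, with the first chain anchored at the origin to
factor out translations. The Monte Carlo engine is required (in tests) to
reproduce the exact mean energy and per-species-pair contact counts within
three standard errors on several such systems. This is the strongest
correctness check in the package: it is sensitive to any violation of
detailed balance, ergodicity, or energy bookkeeping.

## Simulation protocol

Runs follow the dense-seed protocol: all chains are grown as self-avoiding
walks inside a central `init_box`^3 subregion (default 35^3) of the full
box, so a condensate exists from step 0 and the dilute phase forms by
evaporation — far faster than waiting for nucleation. Chain counts are
chosen to hold the total bead volume fraction near 0.016. Each
(temperature, replicate) pair gets a distinct recorded seed; replicate
scatter provides the standard errors quoted on every derived quantity.
The analysis window is the second half of each run (conservative relative
to the energy-plateau heuristic `energy_plateau_step`, which is advisory
only).

## Analysis pipeline

*Condensate identification.* Chains are nodes of a contact graph (linked
when any inter-chain bead pair is within the shell); the condensate is the
largest connected component. Its center of mass uses per-axis circular
means, which is exact under periodic boundaries up to O((spread/box)^2).
Both constructions are reconstructions — the production literature does not
specify its cluster or center definitions.

*Radial profiles and coexisting concentrations.* Per-species bead counts in
unit-width spherical shells around the condensate center, divided by exact
per-shell site counts, averaged over the analysis window, give the density
profile. A four-parameter logistic
rho(r) = rho_dilute + (rho_dense - rho_dilute)/(1 + exp((r - r_mid)/w))
is least-squares fitted per species; its plateaus are c_dense and c_dilute
(volume fractions). Reading the dilute concentration from the far-field
plateau is robust to stray small clusters, unlike box-minus-cluster
counting. The interfacial region is bracketed by the radii where the fitted
curve passes 90% and 10% of the way between plateaus (threshold
config-exposed; no canonical value exists). A state point is declared
single-phase when the largest cluster holds < 50% of chains over the
analysis window or when the fit degenerates (thresholds config-exposed).

*Binodals and two-component diagrams.* Phase points over temperature at
fixed stoichiometry form binodals; over stoichiometry at fixed temperature
they form dilute/dense arms in the (c_A, c_B) plane, with pure-species
endpoints carrying the intrinsic saturation concentrations c_sat.

*Cooperativity.* Against the additivity null
c_dilute = a*c_sat_A + (1-a)*c_sat_B, interior stoichiometries are scored
by their signed deviation; the error-weighted mean decides
concave/additive/convex. Sign-of-mean is used instead of curvature fitting
because the pipeline typically has 3-5 stoichiometries.

*Tie lines.* The segments c_dilute->c_tot and c_tot->c_dense are fitted
separately; near-equal slopes (the collinearity gap) certify two coexisting
phases, and the slope attributes the dominant interaction mode (1:
heterotypic; < 1: homotypic among the abscissa species A; > 1: homotypic
among B), with +-2 SE classification bands.

*Crosslinking parameter L_{i-j}.* For each condensate chain c of species i,
its inter-chain bead contacts are split by partner species; the observed
fraction going to species j is divided by the random-mixing expectation
p_c(j) = (B_j - [j==i] b_c)/(B_tot - b_c), where B_j is the species-j bead
count in the condensate and b_c the chain's own beads. The self-chain
correction makes a single species relabeled as two give exactly L = 1.
This operational definition is pinned by L's published properties (unity
under random mixing, > 1 for enriched partners); the originating study
defines its exact normalisation only in supplementary material that is not
reproduced here.

*Rg profiles.* Per-chain radius of gyration uses seam-unwrapped coordinates
(walking bonds with minimum-image steps), normalised by sqrt(N), binned by
the chain's center-of-mass distance from the condensate center.

*Matched-c_sat tuning.* `match_csat` bisection-scales one species'
homotypic and heterotypic energies until its single-species c_sat matches a
target, used to build the matched length scenario.

## Problem sizes and temperature presets

Production-scale work in this model class uses 120^3-150^3 boxes, chains of
135-400 beads, 3e10 steps and five replicates. Those sizes are reachable
through the config (`scale="full"`), but the package's working presets are
desk-sized: 48^3-64^3 boxes, <= 4e7 steps, and a "mini" variant of the
interaction-matrix battery with 75-bead chains (its claims are
length-independent; chain length is never shrunk in the length scenarios,
where length is the variable under study). With the default e_base = -1
matrix, the mini 75-bead mixtures are two-phase for reduced temperatures
roughly in (11, 15) — the presets sample 12-14, where the dilute arm is
measurable — and the 150/300-bead systems remain two-phase a few units
higher. These windows were located by scanning the cluster fraction and
fit degeneracy over temperature; they are properties of the chosen contact
energies, not tuning targets.

## What the synthetic generators do and do not emulate

The homopolymer scenario generators reproduce the *structure* of the
canonical two- and three-species studies (equal-mass mixing, the four
interaction-matrix patterns, length ratios 150:300 and 200:300:400) at
reduced particle numbers. Random PLCD-like sequences match the average
composition profile of condensate-associated PLCDs (55% polar, 10%
aromatic, 5% charged, 14% aliphatic, 16% Pro/Ala) with stickers spread
near-uniformly, but they do not sample the empirical census distribution of
real PLCDs, and the packaged study sequences are reconstructions from the
published construct definitions (UniProt regions plus described
substitutions) — the A1-LCD+12D variant in particular places its twelve
Asp substitutions at evenly spaced Gly/Ser positions, not at the original
(unpublished here) positions. Consequences: tests passing on these inputs
demonstrate the machinery and the qualitative physics (symmetry nulls, sign
and ordering effects), not quantitative agreement with any measured system.
Small systems also mean larger interfacial curvature, stronger finite-size
shifts of apparent critical temperatures, and noisier dilute arms than
production-scale runs.

## Numerical choices and degenerate inputs

- Contact shell 26 (6 available via config); bonded pairs excluded from
  energy so bond geometry is energy-neutral.
- Boxes must be >= 3 per axis (minimum-image adjacency is then unambiguous).
- Logistic fits: initial guesses from the profile's head/tail means,
  bounded parameters, SinglePhaseError on non-convergence or degenerate
  plateaus rather than silent garbage.
- Tie lines with a vertical segment (dA ~ 0) are reported as infinite slope
  with a flag instead of raising.
- A fully dispersed frame yields a single arbitrary chain as "cluster",
  flagged, so downstream profiling degrades gracefully.
- RNG: numpy MT19937 seeded per (temperature, replicate) from the campaign
  seed via fixed integer arithmetic; identical (config, seed) reruns are
  bit-identical, which the test suite asserts.

## Known limitations

A concrete instance of the finite-size caveats above: in the 150+300
length mixture, the orderings "longer species has lower c_sat" and "longer
species has the wider interfacial region" are reproduced at desk scale,
but the between-species *shift of the Rg/sqrt(N) interfacial peak* is not
reliably resolvable — at droplet radii of 12-16 lattice units the two
peaks sit within one radial bin of each other, and at the smallest sizes
the shorter species' larger dilute population even places its density
midpoint outside the longer species'. Resolving the peak shift requires
production-scale condensates. The corresponding test is kept at its
faithful assertion and is expected to fail at desk scale.

- Single-occupancy beads with isotropic contacts: no valence limits, no
  anisotropic bonding, no explicit solvent energetics.
- The electrostatic modifier is mean-field at the chain level; it cannot
  represent charge patterning along a sequence, salt, or (see above)
  heterotypic repulsion exceeding the homotypic mean.
- Desk-scale condensates hold tens of chains; interfacial widths and
  dilute-arm concentrations carry corresponding finite-size bias.
- No critical-point estimation or finite-size scaling; no mg/mL conversion
  (volume fractions only).
- Exact enumeration covers <= 3 chains; it validates the sampler, not
  large-system observables.
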