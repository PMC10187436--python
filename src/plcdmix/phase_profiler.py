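"""From trajectories to coexistence data.

The condensate in a frame is the largest connected component of the
chain-contact graph (two chains are linked when any inter-chain bead pair
sits within the neighbor shell).  Radial density profiles are accumulated
around its periodic-boundary-aware center of mass, normalised by the exact
number of lattice sites in each spherical shell, and fitted with a
four-parameter logistic

    rho(r) = rho_dilute + (rho_dense - rho_dilute) / (1 + exp((r - r_mid)/w)).

The fit's plateaus are the per-species coexisting concentrations (volume
fractions); the radii where the fitted curve passes 90% and 10% of the way
from the dense to the dilute plateau bracket the interfacial region.
Binodals and fixed-temperature two-component phase diagrams are assembled
from these per-state-point fits, with standard errors across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .energy_model import shell_offsets

__all__ = [
    "SinglePhaseError",
    "LogisticFit",
    "RadialProfile",
    "PhasePoint",
    "chain_adjacency",
    "largest_cluster",
    "condensate_com",
    "radial_density",
    "fit_logistic",
    "coexisting_concentrations",
    "analyze_state_point",
    "build_binodal",
    "two_component_diagram",
    "phase_points_table",
]


class SinglePhaseError(RuntimeError):
    """The state point shows no dense/dilute coexistence."""


# ---------------------------------------------------------------------------
# Cluster identification and center of mass
# ---------------------------------------------------------------------------


def chain_adjacency(frame, neighbor_shell: int = 26) -> np.ndarray:
    """Boolean chain-contact matrix: True when any inter-chain pair touches."""
    box = np.asarray(frame.box, dtype=np.int64)
    n = len(frame.chains)
    occupied = {}
    for ci, (_, coords) in enumerate(frame.chains):
        for xyz in np.asarray(coords) % box:
            occupied[tuple(int(v) for v in xyz)] = ci
    offs = shell_offsets(neighbor_shell)
    adj = np.zeros((n, n), dtype=bool)
    for ci, (_, coords) in enumerate(frame.chains):
        for xyz in np.asarray(coords) % box:
            for off in offs:
                cj = occupied.get(tuple(int(v) for v in (xyz + off) % box))
                if cj is not None and cj != ci:
                    adj[ci, cj] = adj[cj, ci] = True
    return adj


def largest_cluster(frame, neighbor_shell: int = 26) -> tuple[list[int], bool]:
    """Chain indices of the largest connected component.

    Returns ``(chain_indices, dispersed)``; a fully dispersed frame returns a
    single arbitrary chain with ``dispersed=True``.  The result is memoised
    on the frame (several analyses visit the same frames).
    """
    cache = getattr(frame, "_cluster_cache", None)
    if cache is not None and cache[0] == neighbor_shell:
        return cache[1], cache[2]
    adj = chain_adjacency(frame, neighbor_shell)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    biggest = int(sizes.argmax())
    members = [int(i) for i in np.flatnonzero(labels == biggest)]
    dispersed = sizes.max() == 1
    if dispersed:
        members = members[:1]
    frame._cluster_cache = (neighbor_shell, members, dispersed)
    return members, dispersed


def condensate_com(frame, cluster: list[int]) -> np.ndarray:
    """Periodic center of mass of cluster beads via per-axis circular means."""
    if not cluster:
        raise ValueError("cluster must be non-empty")
    box = np.asarray(frame.box, dtype=float)
    pts = np.vstack([np.asarray(frame.chains[ci][1]) for ci in cluster])
    theta = 2.0 * np.pi * pts / box
    mean_sin = np.sin(theta).mean(axis=0)
    mean_cos = np.cos(theta).mean(axis=0)
    ang = np.arctan2(mean_sin, mean_cos)
    return (box * ang / (2.0 * np.pi)) % box


# ---------------------------------------------------------------------------
# Radial profiling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticFit:
    rho_dense: float
    rho_dilute: float
    r_mid: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.rho_dense < self.rho_dilute:
            raise ValueError("rho_dense must be >= rho_dilute")

    def __call__(self, r):
        return self.rho_dilute + (self.rho_dense - self.rho_dilute) / (
            1.0 + np.exp((np.asarray(r, dtype=float) - self.r_mid) / self.width)
        )

    def interfacial_interval(self, thresholds=(0.9, 0.1)) -> tuple[float, float]:
        """Radii where the curve passes the given fractions of the way from
        the dense to the dilute plateau (default 90%/10%)."""
        hi, lo = thresholds
        x_lo = np.log(1.0 / hi - 1.0)
        x_hi = np.log(1.0 / lo - 1.0)
        return (self.r_mid + self.width * x_lo, self.r_mid + self.width * x_hi)


@dataclass
class RadialProfile:
    """Per-species binned densities (beads per site) around the condensate."""

    bin_centers: np.ndarray
    density: dict  # species -> array of volume fractions per bin
    n_frames: int = 0
    fits: dict = field(default_factory=dict)
    interfacial: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, d in self.density.items():
            d = np.asarray(d)
            if d.min() < -1e-12 or d.max() > 1 + 1e-12:
                raise ValueError(f"density of {sp!r} outside [0, 1]")


def _shell_site_counts(box, com, edges) -> np.ndarray:
    box = np.asarray(box)
    ax = []
    for d in range(3):
        x = np.arange(box[d], dtype=float)
        dd = (x - com[d] + box[d] / 2.0) % box[d] - box[d] / 2.0
        ax.append(dd**2)
    d2 = ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]
    r = np.sqrt(d2).ravel()
    idx = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, len(edges) - 2)
    return np.bincount(idx, minlength=len(edges) - 1)


def radial_density(frames, species: list[str] | None = None,
                   neighbor_shell: int = 26, bin_width: float = 1.0) -> RadialProfile:
    """Average per-species radial density over the given frames.

    Each frame contributes spherical-shell bead counts around that frame's
    condensate center of mass, divided by the exact shell site counts.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    box = np.asarray(frames[0].box, dtype=float)
    r_max = float(np.linalg.norm(box / 2.0))
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    n_bins = len(edges) - 1
    if species is None:
        species = []
        for label, _ in frames[0].chains:
            if label not in species:
                species.append(label)
    acc = {sp: np.zeros(n_bins) for sp in species}
    for frame in frames:
        cluster, _ = largest_cluster(frame, neighbor_shell)
        com = condensate_com(frame, cluster)
        sites = _shell_site_counts(frame.box, com, edges).astype(float)
        sites[sites == 0] = np.inf
        for label, coords in frame.chains:
            pts = np.asarray(coords, dtype=float)
            d = (pts - com + box / 2.0) % box - box / 2.0
            r = np.sqrt((d**2).sum(axis=1))
            idx = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_bins - 1)
            cnt = np.bincount(idx, minlength=n_bins).astype(float)
            acc[label] += cnt / sites
    density = {sp: acc[sp] / len(frames) for sp in species}
    return RadialProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=density,
        n_frames=len(frames),
    )


def fit_logistic(profile: RadialProfile, species: str,
                 thresholds=(0.9, 0.1), min_contrast: float = 3.0) -> LogisticFit:
    """Least-squares logistic fit of one species' radial density.

    Raises :class:`SinglePhaseError` when the fit fails to converge or when
    the plateaus are degenerate (dense < ``min_contrast`` x dilute and the
    absolute contrast is tiny), marking the state point single-phase.
    """
    r = np.asarray(profile.bin_centers, dtype=float)
    rho = np.asarray(profile.density[species], dtype=float)
    if len(r) < 8:
        raise ValueError("profile needs at least 8 bins")

    head = max(2, len(rho) // 10)
    rho_dense0 = float(rho[:head].mean())
    rho_dil0 = float(rho[-max(3, len(rho) // 4):].mean())
    contrast = rho_dense0 - rho_dil0
    if contrast <= 0 or (rho_dense0 < min_contrast * max(rho_dil0, 1e-12)
                         and contrast < 1e-3):
        raise SinglePhaseError(
            f"degenerate plateaus for {species!r}: dense~{rho_dense0:.3g}, "
            f"dilute~{rho_dil0:.3g}"
        )
    half = rho_dil0 + 0.5 * contrast
    below = np.flatnonzero(rho < half)
    r_mid0 = float(r[below[0]]) if len(below) else float(r[len(r) // 2])

    def model(rr, rho_dense, rho_dilute, r_mid, width):
        return rho_dilute + (rho_dense - rho_dilute) / (1.0 + np.exp((rr - r_mid) / width))

    try:
        popt, _ = optimize.curve_fit(
            model, r, rho,
            p0=(rho_dense0, rho_dil0, r_mid0, max(1.0, 0.05 * r.max())),
            bounds=([0.0, 0.0, 0.0, 1e-6], [1.0, 1.0, float(r.max()), float(r.max())]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise SinglePhaseError(f"logistic fit did not converge for {species!r}") from exc
    fit = LogisticFit(*[float(v) for v in popt])
    if fit.rho_dense - fit.rho_dilute < 1e-12:
        raise SinglePhaseError(f"degenerate fitted plateaus for {species!r}")
    return fit


# ---------------------------------------------------------------------------
# Coexistence points, binodals, two-component diagrams
# ---------------------------------------------------------------------------


@dataclass
class PhasePoint:
    """Per-species coexisting concentrations at one temperature.

    Concentrations are volume fractions; errors are standard errors about
    the replicate mean.
    """

    temperature: float
    species: list
    c_dilute: dict
    c_dense: dict
    se_dilute: dict
    se_dense: dict
    n_replicates: int = 1

    def __post_init__(self) -> None:
        for sp in self.species:
            if self.c_dense[sp] + 1e-12 < self.c_dilute[sp]:
                raise ValueError(f"c_dense < c_dilute for species {sp!r}")

    def total_dilute(self) -> float:
        return float(sum(self.c_dilute.values()))

    def total_dense(self) -> float:
        return float(sum(self.c_dense.values()))


def coexisting_concentrations(profiles: list[RadialProfile], temperature: float,
                              species: list[str] | None = None,
                              thresholds=(0.9, 0.1)) -> PhasePoint:
    """Phase point from per-replicate radial profiles (one profile each).

    Fits each replicate's profile per species; dense and dilute plateaus
    become c_dense and c_dilute with standard errors across replicates.
    Raises :class:`SinglePhaseError` if any species' fit degenerates in
    every replicate.
    """
    if species is None:
        species = list(profiles[0].density)
    vals = {sp: {"dil": [], "den": []} for sp in species}
    for prof in profiles:
        for sp in species:
            try:
                fit = fit_logistic(prof, sp, thresholds)
            except SinglePhaseError:
                continue
            prof.fits[sp] = fit
            prof.interfacial[sp] = fit.interfacial_interval(thresholds)
            vals[sp]["dil"].append(fit.rho_dilute)
            vals[sp]["den"].append(fit.rho_dense)
    c_dil, c_den, se_dil, se_den = {}, {}, {}, {}
    for sp in species:
        dil, den = vals[sp]["dil"], vals[sp]["den"]
        if not dil:
            raise SinglePhaseError(f"species {sp!r} single-phase in all replicates")
        c_dil[sp] = float(np.mean(dil))
        c_den[sp] = float(np.mean(den))
        se_dil[sp] = float(np.std(dil, ddof=1) / np.sqrt(len(dil))) if len(dil) > 1 else 0.0
        se_den[sp] = float(np.std(den, ddof=1) / np.sqrt(len(den))) if len(den) > 1 else 0.0
    return PhasePoint(
        temperature=temperature, species=list(species),
        c_dilute=c_dil, c_dense=c_den, se_dilute=se_dil, se_dense=se_den,
        n_replicates=len(profiles),
    )


def analyze_state_point(trajectories, neighbor_shell: int = 26,
                        bin_width: float = 1.0, thresholds=(0.9, 0.1),
                        min_cluster_fraction: float = 0.5):
    """Profile replicates of one (T, stoichiometry) state point.

    Returns ``(phase_point, mean_profile, replicate_profiles)``.  The state
    point is declared single-phase (raising :class:`SinglePhaseError`) when
    the largest cluster holds fewer than ``min_cluster_fraction`` of the
    chains in the analysis window, or when every replicate's fit degenerates.
    """
    trajectories = list(trajectories)
    temps = {t.temperature for t in trajectories}
    if len(temps) != 1:
        raise ValueError("state point must have a single temperature")
    frac = []
    profiles = []
    for traj in trajectories:
        frames = traj.analysis_frames()
        n_chains = len(frames[0].chains)
        sizes = [len(largest_cluster(f, neighbor_shell)[0]) for f in frames]
        frac.append(np.mean(sizes) / n_chains)
        profiles.append(radial_density(frames, neighbor_shell=neighbor_shell,
                                       bin_width=bin_width))
    if np.mean(frac) < min_cluster_fraction:
        raise SinglePhaseError(
            f"largest cluster holds {np.mean(frac):.0%} of chains "
            f"(< {min_cluster_fraction:.0%}); single phase"
        )
    point = coexisting_concentrations(profiles, temps.pop(), thresholds=thresholds)
    species = list(profiles[0].density)
    mean_profile = RadialProfile(
        bin_centers=profiles[0].bin_centers,
        density={sp: np.mean([p.density[sp] for p in profiles], axis=0)
                 for sp in species},
        n_frames=sum(p.n_frames for p in profiles),
    )
    for sp in species:
        try:
            fit = fit_logistic(mean_profile, sp, thresholds)
            mean_profile.fits[sp] = fit
            mean_profile.interfacial[sp] = fit.interfacial_interval(thresholds)
        except SinglePhaseError:
            pass
    return point, mean_profile, profiles


def build_binodal(trajectories_by_T: dict, **kwargs) -> tuple[list[PhasePoint], list]:
    """Phase points over temperature at fixed stoichiometry.

    ``trajectories_by_T`` maps temperature -> list of replicate trajectories.
    Single-phase temperatures are excluded and reported in the second return
    value as ``(temperature, reason)`` notes.
    """
    points, notes = [], []
    for T in sorted(trajectories_by_T):
        try:
            point, _, _ = analyze_state_point(trajectories_by_T[T], **kwargs)
            points.append(point)
        except SinglePhaseError as exc:
            notes.append((T, str(exc)))
    return points, notes


def two_component_diagram(points_by_stoichiometry: dict) -> "pd.DataFrame":
    """Dilute- and dense-arm point sets in the (c_A, c_B) plane.

    ``points_by_stoichiometry`` maps the fraction of species A (by chains or
    mass, caller's convention) -> PhasePoint of a two-species system; the
    pure endpoints a=1 and a=0 carry the intrinsic c_sat values.
    """
    import pandas as pd

    rows = []
    for a, point in sorted(points_by_stoichiometry.items()):
        if len(point.species) > 2:
            raise ValueError("two_component_diagram expects <= 2 species")
        sa = point.species[0]
        sb = point.species[1] if len(point.species) > 1 else None
        rows.append({
            "fraction_A": a,
            "c_dilute_A": point.c_dilute.get(sa, 0.0),
            "c_dilute_B": point.c_dilute.get(sb, 0.0) if sb else 0.0,
            "c_dense_A": point.c_dense.get(sa, 0.0),
            "c_dense_B": point.c_dense.get(sb, 0.0) if sb else 0.0,
            "se_dilute_A": point.se_dilute.get(sa, 0.0),
            "se_dilute_B": point.se_dilute.get(sb, 0.0) if sb else 0.0,
            "se_dense_A": point.se_dense.get(sa, 0.0),
            "se_dense_B": point.se_dense.get(sb, 0.0) if sb else 0.0,
            "temperature": point.temperature,
        })
    return pd.DataFrame(rows)


def phase_points_table(points: list[PhasePoint]) -> "pd.DataFrame":
    """Binodal as a tidy table: one row per (T, species)."""
    import pandas as pd

    rows = []
    for p in points:
        for sp in p.species:
            rows.append({
                "temperature": p.temperature,
                "species": sp,
                "c_dilute": p.c_dilute[sp],
                "se_dilute": p.se_dilute[sp],
                "c_dense": p.c_dense[sp],
                "se_dense": p.se_dense[sp],
                "n_replicates": p.n_replicates,
            })
    return pd.DataFrame(rows)
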