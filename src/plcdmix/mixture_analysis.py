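"""Mixture-specific statistics of two-component condensates.

Four analyses live here:

* the additivity null ``c_dilute = a*c_sat_A + (1-a)*c_sat_B`` and the
  concave/convex (positive/negative cooperativity) classification of dilute
  arms against it;
* tie-line extraction from (c_dilute, c_tot, c_dense) in the (c_A, c_B)
  plane, the two-segment collinearity check, and slope-based attribution of
  the dominant interaction mode (slope 1: heterotypic; < 1: homotypic A;
  > 1: homotypic B — species A on the abscissa);
* the crosslinking parameter L_{i-j}: the observed fraction of species-i
  inter-chain bead contacts made with species j, divided by the random-mixing
  expectation given the condensate's composition.  L = 1 means random
  mixing; L > 1 an enrichment of i-j contacts;
* radius-of-gyration profiles: per-chain Rg (seam-unwrapped), normalised by
  sqrt(N), binned by the chain's distance from the condensate center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_model import shell_offsets
from .phase_profiler import condensate_com, largest_cluster

__all__ = [
    "TieLineResult",
    "CrosslinkStats",
    "RgProfile",
    "CooperativityResult",
    "additivity_null",
    "classify_cooperativity",
    "tie_line",
    "crosslink_parameter",
    "crosslink_stats",
    "rg_profile",
    "chain_rg",
    "match_csat",
]


# ---------------------------------------------------------------------------
# Additivity null and cooperativity
# ---------------------------------------------------------------------------


def additivity_null(c_sat_A: float, c_sat_B: float, a: float) -> float:
    """Expected total dilute concentration with zero cooperativity.

    ``a`` is the fraction of species A in the mixture; the null is the
    straight line between the two intrinsic saturation concentrations.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("mixing fraction a must lie in [0, 1]")
    if c_sat_A <= 0 or c_sat_B <= 0:
        raise ValueError("c_sat values must be positive")
    return a * c_sat_A + (1.0 - a) * c_sat_B


@dataclass
class CooperativityResult:
    classification: str  # positive | additive | negative
    deviations: list  # (a, observed_total, null_total, signed deviation, se)
    mean_deviation: float
    se_mean: float


def classify_cooperativity(dilute_points, c_sat_A: float, c_sat_B: float,
                           n_sigma: float = 2.0) -> CooperativityResult:
    """Classify a dilute arm as concave (positive cooperativity), additive,
    or convex (negative cooperativity).

    ``dilute_points`` is an iterable of ``(a, total_c_dilute, se)`` for the
    interior stoichiometries (0 < a < 1); the pure endpoints enter through
    ``c_sat_A``/``c_sat_B``.  Each point's signed deviation is the observed
    total minus the additivity null at its mixing fraction; the class is
    decided by the error-weighted mean deviation (negative = below the null
    = concave = positive cooperativity).
    """
    pts = [(float(a), float(c), float(se)) for a, c, se in dilute_points]
    if not pts:
        raise ValueError("need at least one interior stoichiometry")
    if any(not 0.0 < a < 1.0 for a, _, _ in pts):
        raise ValueError("interior points must have 0 < a < 1")
    devs = []
    w, d = [], []
    for a, c, se in pts:
        null = additivity_null(c_sat_A, c_sat_B, a)
        dev = c - null
        devs.append((a, c, null, dev, se))
        d.append(dev)
        w.append(1.0 / se**2 if se > 0 else None)
    if any(x is None for x in w):
        w = np.ones(len(d))
    w = np.asarray(w, dtype=float)
    d = np.asarray(d, dtype=float)
    mean = float((w * d).sum() / w.sum())
    se_mean = float(np.sqrt(1.0 / w.sum())) if all(x[4] > 0 for x in devs) else (
        float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0
    )
    if se_mean > 0 and abs(mean) < n_sigma * se_mean:
        cls = "additive"
    elif mean < 0:
        cls = "positive"  # below the null line: concave dilute arm
    elif mean > 0:
        cls = "negative"  # above the null line: convex dilute arm
    else:
        cls = "additive"
    return CooperativityResult(cls, devs, mean, se_mean)


# ---------------------------------------------------------------------------
# Tie lines
# ---------------------------------------------------------------------------


@dataclass
class TieLineResult:
    slope_dilute_to_total: float
    slope_total_to_dense: float
    se_dilute_to_total: float
    se_total_to_dense: float
    intercept_dilute_to_total: float
    intercept_total_to_dense: float
    collinearity_gap: float
    collinearity_gap_se: float
    classification: str
    vertical: bool = False


def _segment_slope(p0, p1, se0, se1):
    dA = p1[0] - p0[0]
    dB = p1[1] - p0[1]
    if abs(dA) < 1e-12:
        return np.inf, np.inf, np.nan
    s = dB / dA
    var = (se0[1] ** 2 + se1[1] ** 2) / dA**2 + s**2 * (se0[0] ** 2 + se1[0] ** 2) / dA**2
    intercept = p0[1] - s * p0[0]
    return s, float(np.sqrt(var)), float(intercept)


def tie_line(c_dilute, c_total, c_dense,
             se_dilute=(0.0, 0.0), se_dense=(0.0, 0.0),
             n_sigma: float = 2.0) -> TieLineResult:
    """Two-segment tie line through (c_dilute, c_tot, c_dense) in the
    (c_A, c_B) plane, with slope-based attribution.

    The bulk composition ``c_total`` is treated as exact.  The collinearity
    gap |slope(dilute-total) - slope(total-dense)| with propagated error
    checks that the system forms precisely two coexisting phases (the three
    points are collinear only then).
    """
    s1, e1, b1 = _segment_slope(c_dilute, c_total, se_dilute, (0.0, 0.0))
    s2, e2, b2 = _segment_slope(c_total, c_dense, (0.0, 0.0), se_dense)
    vertical = np.isinf(s1) or np.isinf(s2)
    if vertical:
        return TieLineResult(s1, s2, e1, e2, b1, b2, np.inf, np.inf,
                             "homotypic_B_dominant", vertical=True)
    gap = abs(s1 - s2)
    gap_se = float(np.hypot(e1, e2))
    # attribution: heterotypic when both slopes are within error of 1
    tol1 = max(n_sigma * e1, 1e-12)
    tol2 = max(n_sigma * e2, 1e-12)
    if abs(s1 - 1.0) <= tol1 and abs(s2 - 1.0) <= tol2:
        cls = "heterotypic_dominant"
    else:
        w1 = 1.0 / e1**2 if e1 > 0 else 1.0
        w2 = 1.0 / e2**2 if e2 > 0 else 1.0
        s_mean = (w1 * s1 + w2 * s2) / (w1 + w2)
        cls = "homotypic_A_dominant" if s_mean < 1.0 else "homotypic_B_dominant"
    return TieLineResult(float(s1), float(s2), e1, e2, b1, b2,
                         float(gap), gap_se, cls)


# ---------------------------------------------------------------------------
# Crosslinking parameter L_{i-j}
# ---------------------------------------------------------------------------


def _nan_mean_se(stack: np.ndarray):
    """Mean, standard error and count over axis 0, ignoring NaNs quietly."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        n_ok = np.sum(~np.isnan(stack), axis=0)
        se = np.where(
            n_ok > 1,
            np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1)),
            0.0,
        )
    return mean, se, n_ok


@dataclass
class CrosslinkStats:
    """L matrix over species pairs at one temperature, with replicate SEs."""

    temperature: float
    species: list
    L: np.ndarray
    se: np.ndarray
    defined: np.ndarray  # False where a species was absent from the cluster


def _chain_partner_contacts(frame, cluster, species_order, neighbor_shell=26):
    """Inter-chain bead contacts of each cluster chain, split by partner
    species.  Returns (n_cluster_chains x n_species counts, chain species ids,
    chain bead counts, species bead totals in cluster)."""
    box = np.asarray(frame.box, dtype=np.int64)
    sp_idx = {s: i for i, s in enumerate(species_order)}
    in_cluster = set(cluster)
    occupied = {}
    for ci in cluster:
        label, coords = frame.chains[ci]
        for xyz in np.asarray(coords) % box:
            occupied[tuple(int(v) for v in xyz)] = ci
    offs = shell_offsets(neighbor_shell)
    n_sp = len(species_order)
    counts = np.zeros((len(cluster), n_sp))
    chain_sp = np.empty(len(cluster), dtype=int)
    chain_beads = np.empty(len(cluster), dtype=int)
    beads_per_sp = np.zeros(n_sp)
    pos_in_cluster = {ci: k for k, ci in enumerate(cluster)}
    for k, ci in enumerate(cluster):
        label, coords = frame.chains[ci]
        chain_sp[k] = sp_idx[label]
        chain_beads[k] = len(coords)
        beads_per_sp[sp_idx[label]] += len(coords)
        for xyz in np.asarray(coords) % box:
            for off in offs:
                cj = occupied.get(tuple(int(v) for v in (xyz + off) % box))
                if cj is None or cj == ci:
                    continue
                counts[k, sp_idx[frame.chains[cj][0]]] += 1
    return counts, chain_sp, chain_beads, beads_per_sp


def crosslink_parameter(frames, species_order: list[str],
                        neighbor_shell: int = 26):
    """Aggregate L_{i-j} over frames: observed / expected contact fractions.

    For a chain c of species i, the random-mixing expectation for the
    fraction of its inter-chain contacts made with species j is

        p_c(j) = (B_j - [j == i] * b_c) / (B_tot - b_c),

    where B_j is the bead count of species j in the condensate and b_c the
    chain's own beads — so a single species relabeled into two gives exactly
    L = 1.  Returns ``(L, defined)`` matrices over ``species_order``.
    """
    n_sp = len(species_order)
    obs = np.zeros((n_sp, n_sp))
    exp = np.zeros((n_sp, n_sp))
    for frame in frames:
        cluster, dispersed = largest_cluster(frame, neighbor_shell)
        if dispersed or len(cluster) < 2:
            continue
        counts, chain_sp, chain_beads, beads_sp = _chain_partner_contacts(
            frame, cluster, species_order, neighbor_shell
        )
        total_beads = beads_sp.sum()
        n_contacts = counts.sum(axis=1)
        for k in range(len(cluster)):
            i = chain_sp[k]
            denom = total_beads - chain_beads[k]
            if denom <= 0 or n_contacts[k] == 0:
                continue
            for j in range(n_sp):
                bj = beads_sp[j] - (chain_beads[k] if j == i else 0)
                obs[i, j] += counts[k, j]
                exp[i, j] += n_contacts[k] * bj / denom
    defined = exp > 0
    L = np.full((n_sp, n_sp), np.nan)
    L[defined] = obs[defined] / exp[defined]
    return L, defined


def crosslink_stats(trajectories, species_order: list[str],
                    neighbor_shell: int = 26) -> CrosslinkStats:
    """L_{i-j} averaged over the analysis window, SE across replicates."""
    trajectories = list(trajectories)
    temps = {t.temperature for t in trajectories}
    if len(temps) != 1:
        raise ValueError("trajectories must share a temperature")
    per_rep = []
    for traj in trajectories:
        L, defined = crosslink_parameter(traj.analysis_frames(), species_order,
                                         neighbor_shell)
        per_rep.append(np.where(defined, L, np.nan))
    stack = np.array(per_rep)
    L_mean, L_se, n_ok = _nan_mean_se(stack)
    return CrosslinkStats(
        temperature=temps.pop(),
        species=list(species_order),
        L=L_mean,
        se=L_se,
        defined=n_ok > 0,
    )


# ---------------------------------------------------------------------------
# Radius-of-gyration profiles
# ---------------------------------------------------------------------------


@dataclass
class RgProfile:
    """Mean Rg/sqrt(N) per species vs distance from the condensate center."""

    bin_centers: np.ndarray
    mean: dict  # species -> per-bin mean of Rg/sqrt(N)
    se: dict
    counts: dict


def _unwrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    out = np.array(coords, dtype=float)
    for i in range(1, len(out)):
        d = coords[i] - coords[i - 1]
        d = (d + box // 2) % box - box // 2
        out[i] = out[i - 1] + d
    return out


def chain_rg(coords: np.ndarray, box) -> float:
    """Radius of gyration of one chain, seam-unwrapped along its bonds."""
    box = np.asarray(box, dtype=np.int64)
    u = _unwrap(np.asarray(coords, dtype=np.int64), box)
    com = u.mean(axis=0)
    return float(np.sqrt(((u - com) ** 2).sum(axis=1).mean()))


def rg_profile(trajectories, neighbor_shell: int = 26,
               bin_width: float = 2.0) -> RgProfile:
    """Rg/sqrt(N) versus chain-COM distance from the condensate center.

    All chains contribute (condensate interior through dilute exterior);
    replicate bin means give the standard errors.
    """
    trajectories = list(trajectories)
    box = np.asarray(trajectories[0].frames[0].box, dtype=float)
    r_max = float(np.linalg.norm(box / 2.0))
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)
    species = []
    for label, _ in trajectories[0].frames[0].chains:
        if label not in species:
            species.append(label)
    rep_sums = []
    for traj in trajectories:
        sums = {sp: np.zeros(n_bins) for sp in species}
        cnts = {sp: np.zeros(n_bins) for sp in species}
        for frame in traj.analysis_frames():
            cluster, _ = largest_cluster(frame, neighbor_shell)
            com = condensate_com(frame, cluster)
            for label, coords in frame.chains:
                coords = np.asarray(coords, dtype=np.int64)
                u = _unwrap(coords, np.asarray(frame.box, dtype=np.int64))
                ccom = u.mean(axis=0) % box
                d = (ccom - com + box / 2.0) % box - box / 2.0
                r = float(np.linalg.norm(d))
                b = min(int(r / bin_width), n_bins - 1)
                rg = float(np.sqrt(((u - u.mean(axis=0)) ** 2).sum(axis=1).mean()))
                sums[label][b] += rg / np.sqrt(len(coords))
                cnts[label][b] += 1
        rep_sums.append((sums, cnts))
    mean, se, counts = {}, {}, {}
    for sp in species:
        per_rep = np.full((len(rep_sums), n_bins), np.nan)
        total_cnt = np.zeros(n_bins)
        for r_i, (sums, cnts) in enumerate(rep_sums):
            ok = cnts[sp] > 0
            per_rep[r_i, ok] = sums[sp][ok] / cnts[sp][ok]
            total_cnt += cnts[sp]
        mean[sp], se[sp], _ = _nan_mean_se(per_rep)
        counts[sp] = total_cnt
    return RgProfile(bin_centers=centers, mean=mean, se=se, counts=counts)


def rg_interfacial_peak(rg: RgProfile, species: str, interval,
                        margin: float = 4.0, min_count: int = 5) -> float:
    """Radius of the chain-expansion peak within the interfacial zone.

    Restricts the search to bins inside ``interval`` (an (r_lo, r_hi)
    interfacial bracket) widened by ``margin``, with at least ``min_count``
    chain observations — far-dilute bins hold one or two chains and their
    Rg means are pure noise.
    """
    lo, hi = interval
    ok = (
        (rg.counts[species] >= min_count)
        & (rg.bin_centers >= lo - margin)
        & (rg.bin_centers <= hi + margin)
    )
    if not ok.any():
        raise ValueError(f"no populated bins near the interface for {species!r}")
    vals = np.where(ok, rg.mean[species], -np.inf)
    return float(rg.bin_centers[int(np.argmax(vals))])


# ---------------------------------------------------------------------------
# Matched-c_sat tuning
# ---------------------------------------------------------------------------


def match_csat(csat_fn, target: float, lo: float, hi: float,
               rel_tol: float = 0.1, max_iter: int = 12) -> tuple[float, float]:
    """Bisection on an interaction scale factor until c_sat matches a target.

    ``csat_fn(scale)`` must return the saturation concentration of the tuned
    species when its homotypic and heterotypic energies are multiplied by
    ``scale``; c_sat decreases as the scale (attraction) grows.  Returns
    ``(scale, csat)`` with ``|csat - target| <= rel_tol * target``, or the
    best bracket midpoint after ``max_iter`` iterations.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    f_lo, f_hi = csat_fn(lo), csat_fn(hi)
    if not (min(f_lo, f_hi) <= target <= max(f_lo, f_hi)):
        raise ValueError(
            f"target {target:.3g} not bracketed by csat({lo})={f_lo:.3g}, "
            f"csat({hi})={f_hi:.3g}"
        )
    increasing = f_hi > f_lo
    best = (0.5 * (lo + hi), np.inf)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = csat_fn(mid)
        if abs(f - target) < abs(best[1] - target):
            best = (mid, f)
        if abs(f - target) <= rel_tol * target:
            return mid, f
        if (f < target) == increasing:
            lo = mid
        else:
            hi = mid
    return best
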