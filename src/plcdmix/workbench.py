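"""End-to-end orchestration: config files, the pipeline, the CLI, reports.

A run is described by a single YAML config (either a named scenario or an
explicit species/model/geometry block).  ``run_pipeline`` simulates every
temperature x replicate with recorded per-replicate seeds, writes plain-text
trajectories and TSV tables (binodal, radial profiles, crosslink statistics,
Rg profiles, tie lines), and records everything in a manifest so that runs
are self-describing and resumable.  ``report`` renders figure panels from
the TSVs alone, without recomputation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energy_model import (
    InteractionModel,
    build_scenario_matrix,
    default_plcd_model,
    read_contact_table,
    write_contact_table,
    SCENARIOS,
)
from .lattice_engine import (
    RunConfig,
    energy_plateau_step,
    run_single,
    write_energy_trace,
    write_trajectory_text,
    read_trajectory_text,
)

log = logging.getLogger("plcdmix")
from .mixture_analysis import crosslink_stats, rg_profile, tie_line
from .phase_profiler import (
    SinglePhaseError,
    analyze_state_point,
    phase_points_table,
)
from .sequence_model import PolymerSpecies
from .synthetic_data import ScenarioSpec, SCENARIO_IDS, make_homopolymer_system, study_fixture

__all__ = ["ConfigError", "load_config", "save_config", "run_pipeline",
           "report", "load_manifest", "cli"]


class ConfigError(ValueError):
    """A config schema violation, reported with the offending field path."""


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------


def _species_from_dict(d: dict, i: int) -> PolymerSpecies:
    path = f"species[{i}]"
    try:
        kind = d.get("type", "homopolymer")
        name = d["name"]
        n_chains = int(d.get("n_chains", 0))
        if n_chains < 0:
            raise ConfigError(f"{path}.n_chains: must be >= 0")
        if kind == "homopolymer":
            return PolymerSpecies.homopolymer(
                name, d.get("bead_type", name[:1]), int(d["length"]),
                n_chains, ncpr=float(d.get("ncpr", 0.0)),
            )
        if kind == "sequence":
            return PolymerSpecies.from_sequence(name, d["sequence"], n_chains)
        if kind == "fixture":
            sp = study_fixture(d.get("fixture", name))
            return PolymerSpecies.from_sequence(name, sp.sequence, n_chains)
        raise ConfigError(f"{path}.type: unknown kind {kind!r}")
    except KeyError as exc:
        raise ConfigError(f"{path}.{exc.args[0]}: missing") from None


def _model_from_dict(d: dict, base: Path | None) -> InteractionModel:
    w_el = float(d.get("w_el", 0.0))
    shell = int(d.get("neighbor_shell", 26))
    if "scenario" in d:
        if d["scenario"] not in SCENARIOS:
            raise ConfigError(f"model.scenario: unknown {d['scenario']!r}")
        return build_scenario_matrix(
            d["scenario"], float(d.get("e_base", -1.0)),
            float(d.get("delta", 0.3)),
            bead_types=tuple(d.get("bead_types", ("A", "B"))),
            w_el=w_el,
        )
    if "matrix_file" in d:
        p = Path(d["matrix_file"])
        if base is not None and not p.is_absolute():
            p = base / p
        return read_contact_table(p, w_el=w_el, neighbor_shell=shell)
    if "matrix" in d:
        types = tuple(d["bead_types"])
        return InteractionModel(
            bead_types=types, contact_energy=np.array(d["matrix"], dtype=float),
            w_el=w_el, neighbor_shell=shell,
        )
    if d.get("default") == "plcd":
        return default_plcd_model(w_el=w_el)
    raise ConfigError("model: need one of scenario / matrix / matrix_file / default")


def config_from_dict(d: dict, base: Path | None = None) -> RunConfig:
    if "scenario" in d and "species" not in d:
        spec = ScenarioSpec(d["scenario"], scale=d.get("scale", "desk"),
                            seed=int(d.get("seed", 0)))
        kwargs = {}
        for key in ("e_base", "delta", "matched_scale"):
            if key in d:
                kwargs[key] = float(d[key])
        if "temperatures" in d:
            kwargs["temperatures"] = tuple(float(t) for t in d["temperatures"])
        if "n_replicates" in d:
            kwargs["n_replicates"] = int(d["n_replicates"])
        if "total_steps" in d:
            kwargs["total_steps"] = int(d["total_steps"])
        cfg = make_homopolymer_system(spec, **kwargs)
        if "sample_stride" in d:
            cfg.sample_stride = int(d["sample_stride"])
        return cfg
    for req in ("species", "model", "temperatures"):
        if req not in d:
            raise ConfigError(f"{req}: missing")
    species = [_species_from_dict(s, i) for i, s in enumerate(d["species"])]
    model = _model_from_dict(d["model"], base)
    try:
        cfg = RunConfig(
            species=species,
            model=model,
            box=d.get("box", (48, 48, 48)),
            init_box=int(d.get("init_box", 35)),
            temperatures=tuple(float(t) for t in d["temperatures"]),
            total_steps=int(d.get("total_steps", 1_000_000)),
            sample_stride=d.get("sample_stride"),
            move_weights=d.get("move_weights"),
            n_replicates=int(d.get("n_replicates", 5)),
            seed=int(d.get("seed", 0)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from None
    if cfg.n_replicates < 1:
        raise ConfigError("n_replicates: must be >= 1")
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    species = []
    for sp in cfg.species:
        if sp.is_amino_acid:
            species.append({"name": sp.name, "type": "sequence",
                            "sequence": sp.sequence, "n_chains": sp.n_chains})
        else:
            species.append({
                "name": sp.name, "type": "homopolymer",
                "bead_type": sp.beads[0], "length": sp.n_residues,
                "n_chains": sp.n_chains, "ncpr": sp.ncpr,
            })
    return {
        "species": species,
        "model": {
            "bead_types": list(cfg.model.bead_types),
            "matrix": cfg.model.contact_energy.tolist(),
            "w_el": cfg.model.w_el,
            "neighbor_shell": cfg.model.neighbor_shell,
        },
        "box": list(cfg.box),
        "init_box": cfg.init_box,
        "temperatures": list(cfg.temperatures),
        "total_steps": cfg.total_steps,
        "sample_stride": cfg.stride(),
        "move_weights": cfg.move_weights,
        "n_replicates": cfg.n_replicates,
        "seed": cfg.seed,
        "volume_fraction": cfg.volume_fraction,
    }


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError("config root: expected a mapping")
    return config_from_dict(d, base=path.parent)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _traj_paths(outdir: Path, T: float, rep: int):
    stem = f"T{T:g}_r{rep}"
    return (outdir / "runs" / f"{stem}.traj.txt",
            outdir / "runs" / f"{stem}.energy.tsv")


def run_pipeline(config, outdir, resume: bool = True) -> dict:
    """Simulate, profile and analyze a full campaign; returns the manifest.

    Completed (T, replicate) trajectories found in ``outdir`` are reused
    when ``resume`` is true, making interrupted campaigns restartable.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = config
    outdir = Path(outdir)
    (outdir / "runs").mkdir(parents=True, exist_ok=True)
    (outdir / "analysis").mkdir(exist_ok=True)
    t_start = time.time()
    sequences = {sp.name: sp.beads for sp in cfg.species}
    species_order = [sp.name for sp in cfg.species]

    manifest = {
        "version": __version__,
        "config": config_to_dict(cfg),
        "seeds": {},
        "outputs": {"trajectories": {}, "energy_traces": {}, "analysis": {}},
        "notes": [],
    }

    trajs_by_T: dict = {}
    for ti, T in enumerate(cfg.temperatures):
        trajs_by_T[T] = []
        for rep in range(cfg.n_replicates):
            seed = cfg.replicate_seed(ti, rep)
            manifest["seeds"][f"T{T:g}_r{rep}"] = seed
            tpath, epath = _traj_paths(outdir, T, rep)
            if resume and tpath.exists():
                traj = read_trajectory_text(tpath, sequences)
                traj.analysis_fraction = cfg.analysis_fraction
                log.info("T=%g replicate %d: reusing %s", T, rep, tpath)
            else:
                log.info("T=%g replicate %d: simulating (seed %d)", T, rep, seed)
                traj = run_single(cfg, T, seed)
                traj.replicate = rep
                write_trajectory_text(traj, tpath)
                write_energy_trace(traj, epath)
            plateau = energy_plateau_step(traj.steps, traj.energies)
            window_start = (1.0 - cfg.analysis_fraction) * cfg.total_steps
            if cfg.total_steps and (plateau is None or plateau > window_start):
                note = (f"T={T:g} r{rep}: energy not plateaued before the "
                        f"analysis window (plateau at {plateau})")
                log.warning(note)
                manifest["notes"].append(note)
            manifest["outputs"]["trajectories"][f"T{T:g}_r{rep}"] = str(tpath)
            manifest["outputs"]["energy_traces"][f"T{T:g}_r{rep}"] = str(epath)
            trajs_by_T[T].append(traj)

    # --- analysis: phase points, profiles, crosslinking, Rg ---
    points = []
    for T in cfg.temperatures:
        try:
            point, mean_profile, _ = analyze_state_point(
                trajs_by_T[T], neighbor_shell=cfg.model.neighbor_shell
            )
            points.append(point)
            ppath = outdir / "analysis" / f"profile_T{T:g}.tsv"
            _write_profile(mean_profile, ppath)
            manifest["outputs"]["analysis"][f"profile_T{T:g}"] = str(ppath)
        except SinglePhaseError as exc:
            manifest["notes"].append(f"T={T:g}: single phase ({exc})")
        ls = crosslink_stats(trajs_by_T[T], species_order,
                             cfg.model.neighbor_shell)
        lpath = outdir / "analysis" / f"crosslink_T{T:g}.tsv"
        _write_crosslink(ls, lpath)
        manifest["outputs"]["analysis"][f"crosslink_T{T:g}"] = str(lpath)
        rg = rg_profile(trajs_by_T[T], cfg.model.neighbor_shell)
        rpath = outdir / "analysis" / f"rg_T{T:g}.tsv"
        _write_rg(rg, rpath)
        manifest["outputs"]["analysis"][f"rg_T{T:g}"] = str(rpath)

    if points:
        bpath = outdir / "analysis" / "binodal.tsv"
        phase_points_table(points).to_csv(bpath, sep="\t", index=False)
        manifest["outputs"]["analysis"]["binodal"] = str(bpath)
        if len(species_order) == 2:
            tpath = outdir / "analysis" / "tielines.tsv"
            _write_tielines(points, cfg, tpath)
            manifest["outputs"]["analysis"]["tielines"] = str(tpath)

    manifest["wall_clock_s"] = round(time.time() - t_start, 2)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def _write_profile(profile, path) -> None:
    cols = {"bin_center": profile.bin_centers}
    for sp, dens in profile.density.items():
        cols[f"density_{sp}"] = dens
        if sp in profile.fits:
            cols[f"fit_{sp}"] = profile.fits[sp](profile.bin_centers)
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        for sp, (lo, hi) in profile.interfacial.items():
            fh.write(f"# interfacial_{sp}\t{lo:.4f}\t{hi:.4f}\n")
        for sp, fit in profile.fits.items():
            fh.write(
                f"# fit_{sp}\trho_dense={fit.rho_dense:.6g}\t"
                f"rho_dilute={fit.rho_dilute:.6g}\tr_mid={fit.r_mid:.4f}\t"
                f"width={fit.width:.4f}\n"
            )
        df.to_csv(fh, sep="\t", index=False)


def _write_crosslink(ls, path) -> None:
    rows = []
    for i, si in enumerate(ls.species):
        for j, sj in enumerate(ls.species):
            rows.append({
                "temperature": ls.temperature, "species_i": si, "species_j": sj,
                "L": ls.L[i, j], "se": ls.se[i, j], "defined": bool(ls.defined[i, j]),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_rg(rg, path) -> None:
    cols = {"bin_center": rg.bin_centers}
    for sp in rg.mean:
        cols[f"rg_norm_{sp}"] = rg.mean[sp]
        cols[f"se_{sp}"] = rg.se[sp]
        cols[f"n_{sp}"] = rg.counts[sp]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _write_tielines(points, cfg, path) -> None:
    a, b = cfg.species[0], cfg.species[1]
    v = cfg.box[0] * cfg.box[1] * cfg.box[2]
    c_tot = (a.n_residues * a.n_chains / v, b.n_residues * b.n_chains / v)
    rows = []
    for p in points:
        tl = tie_line(
            (p.c_dilute[a.name], p.c_dilute[b.name]), c_tot,
            (p.c_dense[a.name], p.c_dense[b.name]),
            se_dilute=(p.se_dilute[a.name], p.se_dilute[b.name]),
            se_dense=(p.se_dense[a.name], p.se_dense[b.name]),
        )
        rows.append({
            "temperature": p.temperature,
            "slope_dilute_to_total": tl.slope_dilute_to_total,
            "se_dilute_to_total": tl.se_dilute_to_total,
            "slope_total_to_dense": tl.slope_total_to_dense,
            "se_total_to_dense": tl.se_total_to_dense,
            "collinearity_gap": tl.collinearity_gap,
            "collinearity_gap_se": tl.collinearity_gap_se,
            "classification": tl.classification,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reporting (figures from TSVs only)
# ---------------------------------------------------------------------------


def load_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def report(manifest, outdir) -> list[str]:
    """Render binodal, profile, crosslink and Rg panels from manifest TSVs.

    Returns the list of written figure paths; raises if the manifest has no
    completed analyses, listing what is missing.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(manifest, (str, Path)):
        manifest = load_manifest(manifest)
    analysis = manifest.get("outputs", {}).get("analysis", {})
    missing = [k for k in ("binodal",) if k not in analysis]
    if not analysis:
        raise ValueError(
            "manifest has no analysis outputs; missing stages: "
            "simulate/profile/crosslink"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if "binodal" in analysis:
        df = pd.read_csv(analysis["binodal"], sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        for sp, g in df.groupby("species"):
            ax.errorbar(g["c_dilute"], g["temperature"], xerr=g["se_dilute"],
                        fmt="o-", label=f"{sp} dilute")
            ax.errorbar(g["c_dense"], g["temperature"], xerr=g["se_dense"],
                        fmt="s-", label=f"{sp} dense")
        ax.set_xscale("log")
        ax.set_xlabel("volume fraction")
        ax.set_ylabel("temperature (reduced)")
        ax.legend(fontsize=7)
        p = outdir / "binodal.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(str(p))
    else:
        missing.append("binodal")

    for key, path in sorted(analysis.items()):
        if key.startswith("profile_T"):
            header = {}
            with open(path) as fh:
                for line in fh:
                    if not line.startswith("#"):
                        break
                    parts = line[1:].strip().split("\t")
                    header[parts[0]] = parts[1:]
            df = pd.read_csv(path, sep="\t", comment="#")
            fig, ax = plt.subplots(figsize=(5, 4))
            for col in df.columns:
                if col.startswith("density_"):
                    sp = col[len("density_"):]
                    ax.plot(df["bin_center"], df[col], ".", label=sp)
                    if f"fit_{sp}" in df:
                        ax.plot(df["bin_center"], df[f"fit_{sp}"], "k-", lw=1)
                    if f"interfacial_{sp}" in header:
                        lo, hi = map(float, header[f"interfacial_{sp}"])
                        ax.axvspan(lo, hi, alpha=0.15)
            ax.set_xlabel("r (lattice units)")
            ax.set_ylabel("volume fraction")
            ax.legend(fontsize=7)
            p = outdir / f"{key}.png"
            fig.savefig(p, dpi=150, bbox_inches="tight")
            plt.close(fig)
            written.append(str(p))

    cl_paths = {k: v for k, v in analysis.items() if k.startswith("crosslink_T")}
    if cl_paths:
        df = pd.concat([pd.read_csv(v, sep="\t") for v in cl_paths.values()])
        fig, ax = plt.subplots(figsize=(5, 4))
        for (si, sj), g in df.groupby(["species_i", "species_j"]):
            g = g.sort_values("temperature")
            ax.errorbar(g["temperature"], g["L"], yerr=g["se"], fmt="o-",
                        label=f"L {si}-{sj}")
        ax.axhline(1.0, color="gray", lw=0.8, ls="--")
        ax.set_xlabel("temperature (reduced)")
        ax.set_ylabel("crosslinking parameter L")
        ax.legend(fontsize=7)
        p = outdir / "crosslink.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(str(p))

    for key, path in sorted(analysis.items()):
        if key.startswith("rg_T"):
            df = pd.read_csv(path, sep="\t")
            fig, ax = plt.subplots(figsize=(5, 4))
            for col in df.columns:
                if col.startswith("rg_norm_"):
                    sp = col[len("rg_norm_"):]
                    ok = df[f"n_{sp}"] > 0
                    ax.errorbar(df["bin_center"][ok], df[col][ok],
                                yerr=df[f"se_{sp}"][ok], fmt="o-", label=sp)
            ax.set_xlabel("chain distance from condensate center")
            ax.set_ylabel(r"$R_g/\sqrt{N}$")
            ax.legend(fontsize=7)
            p = outdir / f"{key}.png"
            fig.savefig(p, dpi=150, bbox_inches="tight")
            plt.close(fig)
            written.append(str(p))

    if missing and not written:
        raise ValueError(f"manifest incomplete; missing: {missing}")
    return written


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.version_option(__version__)
def cli():
    """Lattice Monte Carlo phase behaviour of PLCD mixtures."""


@cli.command()
@click.argument("scenario_id", type=click.Choice(SCENARIO_IDS))
@click.option("--scale", default="desk", type=click.Choice(["full", "desk", "mini"]))
@click.option("--seed", default=0, type=int)
@click.option("-o", "--output", default="config.yaml", type=click.Path())
def scenario(scenario_id, scale, seed, output):
    """Write the run config for a named scenario."""
    cfg = make_homopolymer_system(ScenarioSpec(scenario_id, scale=scale, seed=seed))
    save_config(cfg, output)
    click.echo(f"wrote {output} ({cfg.total_beads} beads, "
               f"phi={cfg.volume_fraction:.4f})")


@cli.command()
@click.argument("config_path", type=click.Path(exists=True))
@click.option("-o", "--outdir", default="run_out", type=click.Path())
@click.option("--no-resume", is_flag=True)
def simulate(config_path, outdir, no_resume):
    """Run the full pipeline for a config; writes a manifest."""
    manifest = run_pipeline(config_path, outdir, resume=not no_resume)
    click.echo(f"manifest: {Path(outdir) / 'manifest.yaml'} "
               f"({manifest['wall_clock_s']} s)")


def _rerun_analysis(manifest_path):
    m = load_manifest(manifest_path)
    outdir = Path(manifest_path).parent
    cfg = config_from_dict(m["config"])
    return run_pipeline(cfg, outdir, resume=True)


@cli.command()
@click.argument("manifest_path", type=click.Path(exists=True))
def profile(manifest_path):
    """(Re)compute radial profiles and binodal tables from trajectories."""
    m = _rerun_analysis(manifest_path)
    click.echo("\n".join(f"{k}: {v}" for k, v in m["outputs"]["analysis"].items()))


@cli.command()
@click.argument("manifest_path", type=click.Path(exists=True))
def crosslink(manifest_path):
    """(Re)compute crosslinking statistics from trajectories."""
    m = _rerun_analysis(manifest_path)
    keys = [k for k in m["outputs"]["analysis"] if k.startswith("crosslink")]
    click.echo("\n".join(m["outputs"]["analysis"][k] for k in keys))


@cli.command()
@click.argument("manifest_path", type=click.Path(exists=True))
def tielines(manifest_path):
    """(Re)compute tie lines from trajectories."""
    m = _rerun_analysis(manifest_path)
    key = m["outputs"]["analysis"].get("tielines")
    click.echo(key or "no tie lines (need a two-species, two-phase system)")


@cli.command("report")
@click.argument("manifest_path", type=click.Path(exists=True))
@click.option("-o", "--outdir", default=None, type=click.Path())
def report_cmd(manifest_path, outdir):
    """Render figure panels from a manifest's TSV outputs."""
    outdir = outdir or (Path(manifest_path).parent / "figures")
    for p in report(manifest_path, outdir):
        click.echo(p)


if __name__ == "__main__":
    cli()
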