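"""Structured run configuration and the pipeline driver.

A :class:`RunConfig` captures every tunable of the pipeline stages; it
round-trips losslessly through YAML and rejects unknown keys.  All randomness
flows from the single root seed through named substreams (one per stage),
which the output manifest records together with versions and conventions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["GeneratorConfig", "RefinementConfig", "AnalysisConfig",
           "RunConfig", "load_config", "save_config", "run_pipeline",
           "stage_seed"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorConfig(_Strict):
    n_solute: int = 20
    alpha_fraction: float = 0.4
    water_ratio: int = 63
    number_density: float = 0.103018
    hbond_occupancy: float = 0.5
    hbond_distance_mean: float = 2.28
    hbond_distance_sigma: float = 0.3
    torsion_means: dict = Field(default_factory=lambda: {"phi_H": 22.0, "psi_H": -40.0})
    torsion_sigmas: dict = Field(default_factory=lambda: {"phi_H": 10.0, "psi_H": 10.0})
    rotamer_populations: dict = Field(default_factory=lambda: {
        "omega": [0.45, 0.33, 0.22], "omega_p": [0.39, 0.42, 0.19]})
    rotamer_jitter_sigma: float = 12.0
    n_configurations: int = 10


class RefinementConfig(_Strict):
    feedback_factor: float = 0.1
    amplitude_cap: float = 5.0
    n_outer: int = 5
    steps: int = 2000
    temperature: float = 298.0
    sample_every: int = 50
    cutoff: float = 10.0
    schemes: list = Field(default_factory=lambda: [
        "h-solute_h-water", "d-solute_d-water", "d-solute_h-water"])


class AnalysisConfig(_Strict):
    rdf_dr: float = 0.05
    rdf_pairs: list = Field(default_factory=lambda: [["Ho", "Ow"], ["Oh", "Hw"]])
    hbond_shell: list = Field(default_factory=lambda: [0.0, 2.46])
    intramolecular_shell: list = Field(default_factory=lambda: [1.5, 3.1])
    torsion_windows: dict = Field(default_factory=lambda: {
        "phi_H": [-20.0, 70.0], "psi_H": [-90.0, 10.0]})
    sdf_l_max: int = 8
    sdf_r_max: float = 3.0
    sdf_target: str = "Ow"
    sdf_fraction: float = 0.8


class RunConfig(_Strict):
    stages: list = Field(default_factory=lambda: ["simulate", "rdf", "coord", "torsions"])
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    refinement: RefinementConfig = Field(default_factory=RefinementConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    nmr_constants: str | None = None
    seed: int = 0
    outdir: str = "solvshell_out"


def load_config(path) -> RunConfig:
    return RunConfig(**(yaml.safe_load(Path(path).read_text()) or {}))


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    h = np.uint32(2166136261)
    for ch in f"{stage}:{root_seed}".encode():
        h = np.uint32((int(h) ^ ch) * 16777619 & 0xFFFFFFFF)
    return int(h) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order and write a manifest."""
    from . import __version__, analysis, generator, io

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    known = ["simulate", "targets", "rdf", "coord", "torsions", "sdf"]
    stages = [s for s in known if s in config.stages]
    unknown = set(config.stages) - set(known)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    needs_ensemble = {"rdf", "coord", "torsions", "sdf", "targets"}
    if needs_ensemble & set(stages) and "simulate" not in stages:
        if not (outdir / "ensemble" / "labels.tsv").exists():
            raise ValueError(
                "analysis stages need a simulated ensemble: add the 'simulate' "
                "stage or run it first into the same output directory")
    manifest = {
        "version": __version__,
        "root_seed": config.seed,
        "stages": [],
        "conventions": {
            "F(Q)": "interference-only Faber-Ziman, fm^2",
            "torsion_sign": "IUPAC right-hand rule, (-180, 180]",
            "coordinates": "cartesian angstrom, 0-based indices internally",
        },
    }
    ens = None
    gp = config.generator
    if "simulate" in stages:
        seed = stage_seed(config.seed, "simulate")
        params = generator.GeneratorParams(
            seed=seed,
            **{k: (tuple(v) if isinstance(v, list) else v)
               for k, v in gp.model_dump().items()})
        params.rotamer_populations = {k: tuple(v) for k, v in
                                      params.rotamer_populations.items()}
        ens = generator.generate_ensemble(params)
        io.write_ensemble(ens, outdir / "ensemble")
        manifest["stages"].append({"stage": "simulate", "seed": seed,
                                   "outputs": ["ensemble/"],
                                   "n_configurations": len(ens)})
    if ens is None and needs_ensemble & set(stages):
        ens = io.read_ensemble(outdir / "ensemble")
    ac = config.analysis
    if "targets" in stages:
        seed = stage_seed(config.seed, "targets")
        totals = generator.synthesize_target_fq(ens, noise_sd=0.0, seed=seed,
                                                dr=ac.rdf_dr)
        files = []
        for t in totals:
            f = f"target_{t.scheme}.dat"
            io.write_curve(outdir / f, t.Q, t.F,
                           {"scheme": t.scheme, "convention": "Faber-Ziman fm^2",
                            "columns": "Q_invA F_fm2"})
            files.append(f)
        manifest["stages"].append({"stage": "targets", "seed": seed, "outputs": files})
    if "rdf" in stages:
        files = []
        for pair in ac.rdf_pairs:
            rdf = analysis.compute_rdf(ens, tuple(pair), dr=ac.rdf_dr)
            f = f"rdf_{pair[0]}-{pair[1]}.dat"
            io.write_curve(outdir / f, rdf.r, rdf.g,
                           {"pair": "-".join(pair), "rho": rdf.rho,
                            "c_beta": rdf.c_beta, "columns": "r_A g"})
            files.append(f)
        manifest["stages"].append({"stage": "rdf", "outputs": files})
    if "coord" in stages:
        rows = []
        for pair in ac.rdf_pairs:
            rdf = analysis.compute_rdf(ens, tuple(pair), dr=ac.rdf_dr)
            n = analysis.coordination_number(rdf, *ac.hbond_shell)
            rows.append((f"{pair[0]}-{pair[1]}", n.n_bar))
        rdf_i = analysis.compute_rdf(ens, ("O5p", "HO3"), dr=ac.rdf_dr, mode="intra")
        n_i = analysis.coordination_number(rdf_i, *ac.intramolecular_shell)
        rows.append(("O5p-HO3(intra)", n_i.n_bar))
        lines = ["# pair\tn_bar"] + [f"{a}\t{b!r}" for a, b in rows]
        (outdir / "coordination.tsv").write_text("\n".join(lines) + "\n")
        manifest["stages"].append({"stage": "coord", "outputs": ["coordination.tsv"],
                                   "shell": ac.hbond_shell})
    if "torsions" in stages:
        lines = ["# torsion\tpeak_mean\tgaussian_mean\tgaussian_sigma\tn"]
        for name, window in ac.torsion_windows.items():
            dist = analysis.torsion_statistics(ens, name, tuple(window))
            lines.append(f"{name}\t{dist.peak_mean!r}\t{dist.gaussian_mean!r}"
                         f"\t{dist.gaussian_sigma!r}\t{len(dist.samples)}")
        for name in ("omega", "omega_p"):
            pops = analysis.rotamer_populations_from_samples(
                analysis.collect_torsions(ens, name))
            lines.append(f"{name}_rotamers\tgt={pops.P_gt!r}\tgg={pops.P_gg!r}"
                         f"\ttg={pops.P_tg!r}\t-")
        (outdir / "torsions.tsv").write_text("\n".join(lines) + "\n")
        manifest["stages"].append({"stage": "torsions", "outputs": ["torsions.tsv"]})
    if "sdf" in stages:
        frame = analysis.LocalFrame()
        sdf = analysis.compute_sdf(ens, frame, ac.sdf_target,
                                   r_max=ac.sdf_r_max, l_max=ac.sdf_l_max)
        level = analysis.iso_level_for_fraction(sdf, ac.sdf_fraction)
        proj = analysis.project_sdf(sdf, "yz")
        io.write_matrix(outdir / "sdf_yz.tsv", proj,
                        {"plane": "yz", "iso_level": level,
                         "fraction": ac.sdf_fraction, "n_samples": sdf.n_samples})
        manifest["stages"].append({"stage": "sdf", "outputs": ["sdf_yz.tsv"],
                                   "iso_level": level})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
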