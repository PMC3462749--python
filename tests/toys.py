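"""Shared toy systems for the test suite: small water boxes, MC runners and
the displaced-peak refinement experiment."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from solvshell.analysis import compute_rdf, find_first_maximum
from solvshell.ensemble import (
    Configuration,
    Ensemble,
    SimulationBox,
    build_molecule,
    water_template,
)
from solvshell.generator import IsotopomerScheme, _quat_to_matrix, synthesize_target_fq
from solvshell.refine import EmpiricalPotential, MoveSet, System, default_potential, mc_step

WATER_SCHEMES = [
    IsotopomerScheme("h-water", {"Hw": 0.0}),
    IsotopomerScheme("hdw-water", {"Hw": 0.5}),
    IsotopomerScheme("d-water", {"Hw": 1.0}),
]


def water_box_config(n_waters: int, rho_atoms: float, seed: int) -> Configuration:
    """Random non-overlapping water box at the given atomic number density."""
    rng = np.random.default_rng(seed)
    L = (3 * n_waters / rho_atoms) ** (1.0 / 3.0)
    box = SimulationBox((L, L, L))
    wt = water_template()
    pts = []
    while len(pts) < n_waters:
        c = rng.uniform(0, L, 3)
        if not pts or np.min(np.linalg.norm(
                (np.array(pts) - c + L / 2) % L - L / 2, axis=1)) > 2.4:
            pts.append(c)
    frags = []
    for c in pts:
        w = build_molecule(wt)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w.positions = w.positions @ _quat_to_matrix(q[None])[0].T + c
        frags.append(w)
    return Configuration.from_fragments(box, frags).wrap()


def run_mc(system: System, steps: int, rng, temperature: float = 298.0,
           sample_every: int = 100):
    """Plain MC block; returns (snapshots, acceptance_rate)."""
    ms = MoveSet()
    snaps, acc = [], 0
    for i in range(steps):
        acc += mc_step(system, ms, temperature, rng)
        if (i + 1) % sample_every == 0:
            snaps.append(replace(system.config,
                                 positions=system.config.positions.copy()))
    return snaps, acc / max(steps, 1)


def ensemble_rdf(ens: Ensemble, pair, dr: float = 0.05):
    return compute_rdf(ens, pair, dr=dr,
                       r_max=0.49 * min(ens.box.edge_lengths), mode="inter")


def first_peak(ens: Ensemble, pair, window=(2.0, 4.2)):
    return find_first_maximum(ensemble_rdf(ens, pair), window=window,
                              interpolate=True)


def displaced_seed_system(n_waters: int, rho_atoms: float, seed: int) -> System:
    """Water box whose reference potential carries an S-shaped Ow-Ow
    perturbation (repulsive inside / attractive outside the true first shell),
    displacing the equilibrium first peak outward by roughly 0.3 angstrom."""
    r = np.arange(0.05, 8.0, 0.05)
    pert_u = (2.5 * np.exp(-((r - 2.60) ** 2) / (2 * 0.22 ** 2))
              - 2.5 * np.exp(-((r - 3.20) ** 2) / (2 * 0.22 ** 2)))
    pert = EmpiricalPotential(r, {("Ow", "Ow"): pert_u}, amplitude_cap=10.0)
    return System(water_box_config(n_waters, rho_atoms, seed),
                  default_potential(), reference_perturbation=pert)


def truth_water_targets(n_waters: int = 64, rho_atoms: float = 0.1,
                        seed: int = 1, equil: int = 30000, sample: int = 15000,
                        Q=None):
    """Equilibrated reference water box: (ensemble, per-scheme target F(Q))."""
    Q = np.arange(0.3, 15.0, 0.05) if Q is None else Q
    rng = np.random.default_rng(seed + 10)
    truth = System(water_box_config(n_waters, rho_atoms, seed), default_potential())
    run_mc(truth, equil, rng)
    snaps, _ = run_mc(truth, sample, rng)
    ens = Ensemble(snaps)
    targets = synthesize_target_fq(ens, WATER_SCHEMES, noise_sd=0.0, Q=Q, dr=0.05)
    return ens, targets
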