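"""Empirical-potential structure refinement (simplified).

A Metropolis Monte Carlo engine samples configurations under reference pair
potentials (Lennard-Jones + shifted-force Coulomb with SPC/E-type water and
CHARMM-flavored solute sites) plus flat-bottom harmonic distance restraints
(the H1'-H4 glycosidic restraint at 2.205 A and chair-holding 1-4 distances).
Between Monte Carlo blocks, an empirical pair potential is updated in
proportion to the residual between target and model total structure factors:
the scalar F(Q) residuals of all datasets are deconvolved into per-pair
corrections by ridge-regularized least squares over the Faber-Ziman weights
(2 - delta) c_a c_b b_a b_b (isotopomer contrast is what makes this solvable),
transformed to r-space, scaled by ``feedback_factor x kT`` and clamped to
``amplitude_cap``.  A vanishing residual is a fixed point of the update.

Deviations from production refinement machinery are deliberate desk-scale
choices: shifted-force electrostatics with a 10 A cutoff instead of Ewald,
and a fixed feedback factor with a divergence guard (halved after five
consecutive chi-squared increases) instead of adaptive ceilings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ensemble import Configuration, Ensemble
from .geometry import minimum_image_displacement, rotation_about_axis
from .scattering import TotalStructureFactor, chi_squared, lorch_window

__all__ = [
    "LJSite",
    "PairPotential",
    "EmpiricalPotential",
    "MoveSet",
    "RefinementState",
    "System",
    "default_potential",
    "system_energy",
    "build_system",
    "metropolis_accept",
    "mc_step",
    "update_empirical_potential",
    "refine",
    "KB",
]

KB = 0.008314462618       # kJ / (mol K)
COULOMB = 1389.35458      # kJ mol^-1 A e^-2
CLASH_DISTANCE = 0.1      # below this the energy is clamped, not evaluated
CLASH_ENERGY = 1.0e6


@dataclass(frozen=True)
class LJSite:
    epsilon: float  # kJ/mol
    sigma: float    # A
    charge: float   # e

    def __post_init__(self):
        if self.epsilon < 0 or self.sigma < 0:
            raise ValueError("epsilon >= 0 and sigma >= 0 required")


@dataclass
class PairPotential:
    """Per-site-class Lennard-Jones parameters and partial charges
    (Lorentz-Berthelot combination between classes)."""

    sites: dict  # site_class -> LJSite


def default_potential() -> PairPotential:
    """SPC/E water plus simplified CHARMM-like carbohydrate sites.

    Solute charges are reduced to a neutral, hydrogen-bond-capable set: the
    refinement stage, not the seed force field, is responsible for structure.
    """
    return PairPotential({
        "Ow": LJSite(0.650, 3.166, -0.8476),
        "Hw": LJSite(0.0, 0.0, 0.4238),
        "Cs": LJSite(0.33, 3.56, 0.26667),
        "Hc": LJSite(0.10, 2.40, 0.0),
        "Oh": LJSite(0.65, 3.07, -0.65),
        "Ho": LJSite(0.0, 0.0, 0.40),
        "Oe": LJSite(0.60, 2.90, -0.40),
    })


@dataclass
class EmpiricalPotential:
    """Per-class-pair perturbation potentials on a shared r grid (kJ/mol)."""

    r: np.ndarray
    tables: dict = field(default_factory=dict)  # (a, b) sorted -> U(r)
    amplitude_cap: float = 5.0
    feedback_factor: float = 0.1

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        for pair, U in self.tables.items():
            if np.max(np.abs(U)) > self.amplitude_cap + 1e-9:
                raise ValueError(f"empirical potential for {pair} exceeds the cap")

    def energy(self, pair: tuple, d: np.ndarray) -> np.ndarray:
        key = tuple(sorted(pair))
        U = self.tables.get(key)
        if U is None:
            return np.zeros_like(d)
        return np.interp(d, self.r, U, left=U[0], right=0.0)

    @classmethod
    def zeros(cls, r, amplitude_cap: float = 5.0, feedback_factor: float = 0.1):
        return cls(np.asarray(r, float), {}, amplitude_cap, feedback_factor)


@dataclass
class MoveSet:
    translation: float = 0.25   # A
    rotation: float = 20.0      # deg
    torsion: float = 10.0       # deg
    weights: tuple = (0.5, 0.3, 0.2)

    def __post_init__(self):
        if min(self.translation, self.rotation, self.torsion) <= 0:
            raise ValueError("move steps must be positive")


@dataclass
class RefinementState:
    iteration: int
    chi2_per_dataset: list
    acceptance_rate: float
    n_snapshots: int

    def __post_init__(self):
        if any(c < 0 for c in self.chi2_per_dataset):
            raise ValueError("chi2 must be non-negative")
        if not (0.0 <= self.acceptance_rate <= 1.0):
            raise ValueError("acceptance rate must lie in [0, 1]")


class System:
    """A configuration bound to potentials, restraints and move topology."""

    def __init__(self, config: Configuration, potential: PairPotential,
                 restraints=None, ep: EmpiricalPotential | None = None,
                 cutoff: float = 10.0, torsion_moves: dict | None = None,
                 reference_perturbation: EmpiricalPotential | None = None):
        half = 0.5 * min(config.box.edge_lengths)
        self.cutoff = min(cutoff, half * 0.999)
        self.config = config
        self.potential = potential
        self.restraints = list(restraints or [])  # (i, j, target, tol, k)
        self.ep = ep
        # static tabulated addition to the reference potentials (never updated
        # by refinement; used e.g. to pose deliberately wrong seed structure)
        self.reference_perturbation = reference_perturbation
        self.edges = np.asarray(config.box.edge_lengths)
        classes = config.site_class
        self.eps = np.array([potential.sites[c].epsilon for c in classes])
        self.sig = np.array([potential.sites[c].sigma for c in classes])
        self.q = np.array([potential.sites[c].charge for c in classes])
        self.mol_atoms = {int(m): np.flatnonzero(config.molecule_id == m)
                          for m in np.unique(config.molecule_id)}
        self.mol_ids = sorted(self.mol_atoms)
        # torsion moves: molecule id -> list of (quad, moving_atom_indices)
        self.torsion_moves = torsion_moves or {}
        self.clash_flagged = False

    # -- energy ------------------------------------------------------------

    def _pair_terms(self, ia: np.ndarray, ib: np.ndarray, pos: np.ndarray) -> float:
        disp = minimum_image_displacement(pos[ia, None, :], pos[None, ib, :], self.edges)
        d = np.linalg.norm(disp, axis=-1)
        clash = d < CLASH_DISTANCE
        if clash.any():
            self.clash_flagged = True
        within = (d < self.cutoff) & ~clash
        if not within.any():
            return float(clash.sum()) * CLASH_ENERGY
        di = d[within]
        rows, cols = np.nonzero(within)
        gi, gj = ia[rows], ib[cols]
        sij = 0.5 * (self.sig[gi] + self.sig[gj])
        eij = np.sqrt(self.eps[gi] * self.eps[gj])
        e = 0.0
        lj = eij > 0
        if lj.any():
            sr6 = (sij[lj] / di[lj]) ** 6
            src6 = (sij[lj] / self.cutoff) ** 6
            e += float(np.sum(4 * eij[lj] * ((sr6**2 - sr6) - (src6**2 - src6))))
        qq = self.q[gi] * self.q[gj]
        rc = self.cutoff
        e += float(np.sum(COULOMB * qq * (1.0 / di - 1.0 / rc + (di - rc) / rc**2)))
        for tab in (self.ep, self.reference_perturbation):
            if tab is not None and tab.tables:
                ca, cb = self.config.site_class[gi], self.config.site_class[gj]
                for key in tab.tables:
                    mask = ((ca == key[0]) & (cb == key[1])) | ((ca == key[1]) & (cb == key[0]))
                    if mask.any():
                        e += float(np.sum(tab.energy(key, di[mask])))
        return e + float(clash.sum()) * CLASH_ENERGY

    def molecule_energy(self, mid: int, pos: np.ndarray | None = None) -> float:
        pos = self.config.positions if pos is None else pos
        ia = self.mol_atoms[mid]
        others = np.flatnonzero(self.config.molecule_id != mid)
        e = self._pair_terms(ia, others, pos)
        return e + self.restraint_energy(mid, pos)

    def restraint_energy(self, mid: int | None = None, pos: np.ndarray | None = None) -> float:
        pos = self.config.positions if pos is None else pos
        e = 0.0
        for (i, j, target, tol, k) in self.restraints:
            if mid is not None and self.config.molecule_id[i] != mid:
                continue
            d = np.linalg.norm(
                minimum_image_displacement(pos[i], pos[j], self.edges))
            excess = abs(d - target) - tol
            if excess > 0:
                e += k * excess**2
        return e

    def total_energy(self) -> float:
        pair = sum(self.molecule_energy(m) - self.restraint_energy(m)
                   for m in self.mol_ids) / 2.0
        return pair + self.restraint_energy()


def system_energy(config: Configuration, potential: PairPotential,
                  ep: EmpiricalPotential | None = None, restraints=None,
                  cutoff: float = 10.0) -> float:
    """Total potential energy (kJ/mol) of a configuration (convenience wrapper)."""
    return System(config, potential, restraints, ep, cutoff).total_energy()


def metropolis_accept(delta_u: float, temperature: float, rng) -> bool:
    """The Metropolis criterion: accept with probability min(1, exp(-dU/kT))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_u <= 0:
        return True
    return rng.random() < np.exp(-delta_u / (KB * temperature))


def mc_step(system: System, moveset: MoveSet, temperature: float, rng) -> bool:
    """One Metropolis move: rigid translation/rotation of a random molecule, or
    a torsion pivot on a molecule with named torsions.  Bonded geometry is
    preserved by construction (rigid moves) or by rotating the distal side of
    the torsion bond as a unit."""
    mid = system.mol_ids[rng.integers(len(system.mol_ids))]
    ia = system.mol_atoms[mid]
    pos = system.config.positions
    kind = rng.choice(3, p=np.asarray(moveset.weights) / sum(moveset.weights))
    if kind == 2 and mid not in system.torsion_moves:
        kind = rng.integers(2)
    new = pos.copy()
    if kind == 0:
        new[ia] = pos[ia] + rng.uniform(-moveset.translation, moveset.translation, 3)
    elif kind == 1:
        axis = rng.normal(size=3)
        R = rotation_about_axis(axis, rng.normal(0.0, moveset.rotation))
        center = pos[ia].mean(axis=0)
        new[ia] = (R @ (pos[ia] - center).T).T + center
    else:
        moves = system.torsion_moves[mid]
        quad, moving = moves[rng.integers(len(moves))]
        _, j, k, _ = quad
        R = rotation_about_axis(pos[k] - pos[j], rng.normal(0.0, moveset.torsion))
        new[moving] = (R @ (pos[moving] - pos[k]).T).T + pos[k]
    e0 = system.molecule_energy(mid)
    e1 = system.molecule_energy(mid, new)
    if metropolis_accept(e1 - e0, temperature, rng):
        system.config.positions = new
        return True
    return False


def _inverse_transform(Q: np.ndarray, dS: np.ndarray, r: np.ndarray,
                       rho: float) -> np.ndarray:
    """r-space image of a Q-space residual (same sine kernel as g(r) recovery)."""
    h = dS * lorch_window(Q, Q[-1])
    kernel = np.sin(np.outer(r, Q))
    integral = np.trapezoid(kernel * (Q * h)[None, :], Q, axis=1)
    return integral / (2.0 * np.pi**2 * rho * np.maximum(r, 1e-6))


def update_empirical_potential(targets, models, ep: EmpiricalPotential,
                               rho: float, temperature: float = 298.0,
                               ridge: float = 1e-3):
    """Update the empirical potential from F(Q) residuals.

    Per Q point, the dataset residuals dF_d = F_model - F_target are
    deconvolved into per-pair partial residuals x_p by least squares over the
    Faber-Ziman weight matrix W[d, p] = (2 - delta) c_a c_b b_a^d b_b^d with a
    ridge penalty (ties broken toward zero update).  Each pair's x_p(Q) is
    transformed to r-space, scaled by feedback x kT and added to the table
    under the amplitude cap.  Pairs invisible in every dataset are skipped.

    Returns (new_ep, skipped_pairs).
    """
    Q = targets[0].Q
    comp = targets[0].composition
    classes = sorted(c for c in comp if comp[c] > 0)
    pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i:]]
    W = np.zeros((len(targets), len(pairs)))
    dF = np.zeros((len(targets), len(Q)))
    for d, (tgt, mdl) in enumerate(zip(targets, models)):
        if not np.allclose(tgt.Q, Q) or not np.allclose(mdl.Q, Q):
            raise ValueError("targets and models must share one Q grid")
        dF[d] = mdl.F - tgt.F
        for p, (a, b) in enumerate(pairs):
            delta = 1.0 if a == b else 0.0
            W[d, p] = (2 - delta) * comp[a] * comp[b] * tgt.effective_b[a] * tgt.effective_b[b]
    col = np.linalg.norm(W, axis=0)
    scale = col.max()
    visible = col > 1e-9 * scale
    skipped = [pairs[p] for p in np.flatnonzero(~visible)]
    Wv = W[:, visible]
    lam = ridge * np.trace(Wv.T @ Wv) / Wv.shape[1]
    X = np.linalg.solve(Wv.T @ Wv + lam * np.eye(Wv.shape[1]), Wv.T @ dF)
    kT = KB * temperature
    tables = dict(ep.tables)
    for row, p in enumerate(np.flatnonzero(visible)):
        du = ep.feedback_factor * kT * _inverse_transform(Q, X[row], ep.r, rho)
        U = tables.get(pairs[p], np.zeros_like(ep.r))
        tables[pairs[p]] = np.clip(U + du, -ep.amplitude_cap, ep.amplitude_cap)
    new = EmpiricalPotential(ep.r, tables, ep.amplitude_cap, ep.feedback_factor)
    return new, skipped


def _snapshot(system: System) -> Configuration:
    cfg = system.config
    return replace(cfg, positions=cfg.positions.copy())


def _model_totals(snapshots, targets, dr: float = 0.05):
    """Ensemble-averaged model F(Q) on each target's scheme weighting."""
    from .analysis import compute_rdf
    from . import scattering

    ens = Ensemble(snapshots)
    comp = snapshots[0].composition()
    classes = sorted(comp)
    r_max = 0.49 * min(ens.box.edge_lengths)
    Q = targets[0].Q
    partials = []
    for i, a in enumerate(classes):
        for b in classes[i:]:
            rdf = compute_rdf(ens, (a, b), dr=dr, r_max=r_max, mode="all")
            partials.append(scattering.sq_from_rdf(rdf, Q, window=True))
    out = []
    for tgt in targets:
        out.append(scattering.total_fq(partials, comp, tgt.effective_b,
                                       scheme=tgt.scheme))
    return out


def refine(system: System, targets, n_outer: int = 5, steps: int = 2000,
           temperature: float = 298.0, moveset: MoveSet | None = None,
           sample_every: int = 50, seed: int = 0, rdf_dr: float = 0.05,
           update_ep: bool = True, feedback: float | None = None,
           amplitude_cap: float | None = None,
           initial_ensemble: Ensemble | None = None):
    """Alternate Monte Carlo blocks with empirical-potential updates.

    Returns (ensemble of accumulated post-equilibration configurations,
    list of RefinementState).  The first outer iteration is treated as
    equilibration and not accumulated.  If the mean chi-squared rises for five
    consecutive iterations the feedback factor is halved (divergence guard,
    recorded in the state history via the ``meta`` attribute).
    """
    if not targets:
        raise ValueError("at least one target dataset is required")
    moveset = moveset or MoveSet()
    rng = np.random.default_rng(seed)
    rho = system.config.n_atoms / system.config.box.volume
    if system.ep is None:
        r_grid = np.arange(0.05, 0.49 * min(system.config.box.edge_lengths), 0.05)
        system.ep = EmpiricalPotential.zeros(r_grid)
    if feedback is not None:
        system.ep = replace(system.ep, feedback_factor=feedback)
    if amplitude_cap is not None:
        system.ep = replace(system.ep, amplitude_cap=amplitude_cap)
    history = []
    accumulated = []
    rises = 0
    prev_chi2 = None
    for it in range(n_outer):
        accepted = 0
        snaps = []
        for step in range(steps):
            accepted += mc_step(system, moveset, temperature, rng)
            if (step + 1) % sample_every == 0:
                snaps.append(_snapshot(system))
        if not snaps:
            # no sampling requested this block: fall back to the provided
            # starting ensemble (so self-target refinement sees an exact
            # zero-residual fixed point) or the instantaneous configuration
            snaps = (list(initial_ensemble.configurations) if initial_ensemble
                     else [_snapshot(system)])
        models = _model_totals(snaps, targets, dr=rdf_dr)
        chi2 = [chi_squared(m, t) for m, t in zip(models, targets)]
        mean_chi2 = float(np.mean(chi2))
        if prev_chi2 is not None and mean_chi2 > prev_chi2:
            rises += 1
            if rises >= 5:
                system.ep = replace(system.ep,
                                    feedback_factor=system.ep.feedback_factor / 2)
                rises = 0
        else:
            rises = 0
        prev_chi2 = mean_chi2
        if update_ep:
            system.ep, _ = update_empirical_potential(
                targets, models, system.ep, rho, temperature)
        if it > 0:
            accumulated.extend(snaps)
        history.append(RefinementState(it, chi2, accepted / max(steps, 1), len(snaps)))
    if not accumulated:
        accumulated = snaps
    return Ensemble(accumulated), history


def build_system(config: Configuration, fragments_torsions=None,
                 potential: PairPotential | None = None,
                 restraint_k: float = 500.0, **kwargs) -> System:
    """Assemble a System from a configuration, deriving restraints and torsion
    moves from per-molecule fragment metadata.

    ``fragments_torsions`` maps molecule id -> (torsions dict, restraints list,
    bonds list) in local indices, as produced by the molecule builders.
    """
    potential = potential or default_potential()
    restraints = []
    torsion_moves = {}
    if fragments_torsions:
        for mid, (torsions, frag_restraints, bonds) in fragments_torsions.items():
            atoms = np.flatnonzero(config.molecule_id == mid)
            base = atoms.min()
            for (i, j, target, tol) in frag_restraints:
                restraints.append((base + i, base + j, target, tol, restraint_k))
            moves = []
            adj = {}
            for a, b in bonds:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            for name, (i, j, k, l) in torsions.items():
                seen, stack, out = {j, k}, [k], {k}
                while stack:
                    cur = stack.pop()
                    for nb in adj.get(cur, ()):
                        if nb not in seen:
                            seen.add(nb)
                            out.add(nb)
                            stack.append(nb)
                moving = np.array(sorted(base + m for m in out if m != k))
                moves.append(((base + i, base + j, base + k, base + l), moving))
            if moves:
                torsion_moves[int(mid)] = moves
    return System(config, potential, restraints, torsion_moves=torsion_moves, **kwargs)
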