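"""Synthetic disaccharide-water ensembles with known, tunable structure.

The generator emulates the study conditions of the refined structural model:
a periodic cubic box of 20 disaccharide molecules (8 alpha, 12 beta anomers)
and 1260 waters (1:63 solute:water) at 0.103018 atoms per cubic angstrom.
Structural parameters are *posed* geometrically rather than simulated, so that
every analysis stage can be checked against ground truth:

* glycosidic torsions phi_H / psi_H drawn from Gaussians around the syn
  conformer (defaults 22 and -40 deg),
* hydroxymethyl torsions drawn from a gt/gg/tg categorical with angular jitter,
* an intramolecular O5'...HO3 hydrogen bond present with Bernoulli probability
  ``hbond_occupancy``; when present the hydroxyl proton is posed at a
  Gaussian-distributed distance (default 2.28 +/- 0.3 A, clipped to the
  1.5-3.1 A shell) from the non-reducing ring oxygen, and when absent a water
  hydrogen occupies that shell instead (the donor role is shared with solvent),
* waters otherwise placed uniformly with heavy-atom overlap rejection.

Identical seeds give bit-identical ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ensemble import (
    Configuration,
    Ensemble,
    Fragment,
    SimulationBox,
    build_molecule,
    cellobiose_template,
    water_template,
)
from .geometry import rotation_about_axis
from . import scattering
from .scattering import ScatteringLengthTable, TotalStructureFactor

__all__ = [
    "GeneratorParams",
    "IsotopomerScheme",
    "default_schemes",
    "plan_composition",
    "box_from_density",
    "generate_ensemble",
    "synthesize_target_fq",
    "PackingError",
]

HEAVY_OVERLAP = 2.0    # minimum heavy-atom separation, A
MAX_RETRIES = 10_000
HBOND_SHELL = (1.5, 3.1)


class PackingError(RuntimeError):
    """Raised when placement fails after bounded retries (density too high)."""


@dataclass(frozen=True)
class IsotopomerScheme:
    """Per-exchangeable-class deuterium fractions (the H/D contrast device)."""

    name: str
    deuteration: dict  # exchangeable site class -> D fraction in [0, 1]

    def __post_init__(self):
        for cls, f in self.deuteration.items():
            if cls not in ("Ho", "Hw"):
                raise ValueError(f"{cls!r} is not an exchangeable class")
            if not (0.0 <= f <= 1.0):
                raise ValueError("deuterium fractions must lie in [0, 1]")


def default_schemes() -> list:
    """Seven H/D labeling schemes spanning the (solute hydroxyl x water) axes."""
    mk = IsotopomerScheme
    return [
        mk("h-solute_h-water", {"Ho": 0.0, "Hw": 0.0}),
        mk("d-solute_d-water", {"Ho": 1.0, "Hw": 1.0}),
        mk("d-solute_h-water", {"Ho": 1.0, "Hw": 0.0}),
        mk("h-solute_d-water", {"Ho": 0.0, "Hw": 1.0}),
        mk("h-solute_hdw-water", {"Ho": 0.0, "Hw": 0.5}),
        mk("d-solute_hdw-water", {"Ho": 1.0, "Hw": 0.5}),
        mk("hd-solute_hdw-water", {"Ho": 0.5, "Hw": 0.5}),
    ]


@dataclass
class GeneratorParams:
    n_solute: int = 20
    alpha_fraction: float = 0.4           # 8 of 20 molecules
    water_ratio: int = 63                 # waters per solute
    number_density: float = 0.103018      # atoms / A^3
    hbond_occupancy: float = 0.5          # O5'...HO3 donor share
    hbond_distance_mean: float = 2.28     # A
    hbond_distance_sigma: float = 0.3     # A
    torsion_means: dict = field(default_factory=lambda: {"phi_H": 22.0, "psi_H": -40.0})
    torsion_sigmas: dict = field(default_factory=lambda: {"phi_H": 10.0, "psi_H": 10.0})
    # (P_gt, P_gg, P_tg) per hydroxymethyl torsion
    rotamer_populations: dict = field(default_factory=lambda: {
        "omega": (0.45, 0.33, 0.22), "omega_p": (0.39, 0.42, 0.19)})
    rotamer_jitter_sigma: float = 12.0    # deg
    n_configurations: int = 10
    seed: int = 0

    def __post_init__(self):
        for frac in (self.alpha_fraction, self.hbond_occupancy):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        for pops in self.rotamer_populations.values():
            if abs(sum(pops) - 1.0) > 1e-9:
                raise ValueError("rotamer populations must sum to 1")
            if any(p < 0 for p in pops):
                raise ValueError("rotamer populations must be non-negative")
        if self.hbond_distance_sigma < 0 or any(
                s < 0 for s in self.torsion_sigmas.values()):
            raise ValueError("sigmas must be non-negative")


def plan_composition(n_solute: int, water_ratio: int,
                     alpha_fraction: float = 0.4) -> tuple:
    """(n_alpha, n_beta, n_water) for a solute count and waters-per-solute ratio."""
    if n_solute < 0 or water_ratio < 0:
        raise ValueError("counts must be non-negative")
    n_alpha = int(round(alpha_fraction * n_solute))
    return n_alpha, n_solute - n_alpha, n_solute * water_ratio


def box_from_density(composition: dict, atoms_per_molecule: dict,
                     number_density: float) -> SimulationBox:
    """Cubic box with edge L = (N_atoms / rho)^(1/3)."""
    if number_density <= 0:
        raise ValueError("density must be positive")
    n_atoms = sum(composition[k] * atoms_per_molecule[k] for k in composition)
    if n_atoms == 0:
        raise ValueError("composition contains no atoms")
    L = (n_atoms / number_density) ** (1.0 / 3.0)
    return SimulationBox((L, L, L), periodic=True, number_density=number_density)


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _min_image_ok(candidate_heavy, placed_tree, edges, threshold=HEAVY_OVERLAP):
    if placed_tree is None or candidate_heavy.shape[0] == 0:
        return True
    wrapped = candidate_heavy - np.floor(candidate_heavy / edges) * edges
    d, _ = placed_tree.query(wrapped, k=1)
    return np.min(d) >= threshold


def _pose_proton_at_distance(o3, o5p, target: float, rng, oh: float = 1.0):
    """Place a hydroxyl proton on the 1.0-A sphere around O3, exactly ``target``
    angstrom from O5' (random azimuth about the O3-O5' axis)."""
    u = o5p - o3
    D = np.linalg.norm(u)
    u = u / D
    target = float(np.clip(target, abs(D - oh) + 1e-6, D + oh - 1e-6))
    cos_g = (oh * oh + D * D - target * target) / (2.0 * oh * D)
    cos_g = np.clip(cos_g, -1.0, 1.0)
    sin_g = np.sqrt(1.0 - cos_g * cos_g)
    # orthonormal basis perpendicular to u
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, a)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    az = rng.uniform(0, 2 * np.pi)
    direction = cos_g * u + sin_g * (np.cos(az) * v + np.sin(az) * w)
    return o3 + oh * direction, target


def _draw_torsions(params: GeneratorParams, rng) -> dict:
    t = {}
    for name in ("phi_H", "psi_H"):
        t[name] = rng.normal(params.torsion_means[name], params.torsion_sigmas[name])
    for name in ("omega", "omega_p"):
        pops = params.rotamer_populations[name]
        ref = [65.0, -65.0, 180.0][rng.choice(3, p=np.asarray(pops) / sum(pops))]
        t[name] = ref + rng.normal(0.0, params.rotamer_jitter_sigma)
    return t


def _generate_configuration(params: GeneratorParams, box: SimulationBox,
                            n_alpha: int, n_beta: int, n_water: int,
                            template, water_tmpl, rng) -> Configuration:
    edges = np.asarray(box.edge_lengths)
    fragments = []
    heavy_positions = []

    def heavy_tree():
        if not heavy_positions:
            return None
        pts = np.concatenate(heavy_positions)
        return cKDTree(pts - np.floor(pts / edges) * edges, boxsize=edges)

    anomers = ["alpha"] * n_alpha + ["beta"] * n_beta
    hbond_flags = rng.random(len(anomers)) < params.hbond_occupancy
    special_water_targets = []  # (O5' position, wanted H distance)

    for i, anomer in enumerate(anomers):
        frag = build_molecule(template, anomer, torsions=_draw_torsions(params, rng))
        placed = False
        tree = heavy_tree()
        for _ in range(MAX_RETRIES):
            R = _random_rotation(rng)
            shift = rng.uniform(0, edges)
            pos = frag.positions @ R.T + shift
            heavy = pos[frag.elements != "H"]
            if _min_image_ok(heavy, tree, edges):
                placed = True
                break
        if not placed:
            raise PackingError(
                "solute placement failed after bounded retries; lower the density")
        frag = frag.copy()
        frag.positions = pos
        # pose the HO3 proton relative to the non-reducing ring oxygen
        i_o3, i_ho3, i_o5p = (frag.index_of(r) for r in ("O3", "HO3", "O5p"))
        o3, o5p = frag.positions[i_o3], frag.positions[i_o5p]
        if hbond_flags[i]:
            target = float(np.clip(
                rng.normal(params.hbond_distance_mean, params.hbond_distance_sigma),
                *HBOND_SHELL))
            frag.positions[i_ho3], _ = _pose_proton_at_distance(o3, o5p, target, rng)
        else:
            # point the proton away from O5' (outside the hydrogen-bond shell)
            for _ in range(100):
                h, _ = _pose_proton_at_distance(
                    o3, o5p, np.linalg.norm(o5p - o3) + 0.98, rng)
                if np.linalg.norm(h - o5p) > HBOND_SHELL[1] + 0.1:
                    break
            frag.positions[i_ho3] = h
            # a water hydrogen takes over the donor role in the shell
            dist = float(np.clip(
                rng.normal(params.hbond_distance_mean, params.hbond_distance_sigma),
                *HBOND_SHELL))
            special_water_targets.append((o5p, dist))
        fragments.append(frag)
        heavy_positions.append(frag.positions[frag.elements != "H"])

    # waters donating to unbonded O5' acceptors
    n_special = 0
    for (o5p, dist) in special_water_targets:
        if n_special >= n_water:
            break
        tree = heavy_tree()
        placed = False
        for _ in range(MAX_RETRIES):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            hw = o5p + dist * v
            ow = o5p + (dist + 1.0) * v
            if _min_image_ok(ow[None, :], tree, edges, HEAVY_OVERLAP):
                placed = True
                break
        if not placed:
            raise PackingError("donor-water placement failed; lower the density")
        w = build_molecule(water_tmpl)
        # orient: put one O-H bond exactly along (hw - ow)
        w = _orient_water(w, ow, hw, rng)
        fragments.append(w)
        heavy_positions.append(ow[None, :])
        n_special += 1

    # bulk waters: batch placement with greedy mutual-overlap rejection
    remaining = n_water - n_special
    placed = np.empty((0, 3))
    tree = heavy_tree()
    attempts = 0
    while len(placed) < remaining:
        attempts += 1
        if attempts > 200:
            raise PackingError("water packing failed; lower the density")
        need = remaining - len(placed)
        batch = rng.uniform(0, edges, size=(3 * need + 64, 3))
        if tree is not None:
            d, _ = tree.query(batch, k=1)
            batch = batch[d >= HEAVY_OVERLAP]
        if len(placed):
            d, _ = cKDTree(placed, boxsize=edges).query(batch, k=1)
            batch = batch[d >= HEAVY_OVERLAP]
        if len(batch) == 0:
            continue
        pairs = cKDTree(batch, boxsize=edges).query_pairs(HEAVY_OVERLAP,
                                                          output_type="ndarray")
        keep = np.ones(len(batch), dtype=bool)
        for i, j in pairs:
            if keep[i] and keep[j]:
                keep[j] = False
        kept = batch[keep][:need]
        placed = np.vstack([placed, kept]) if len(placed) else kept
    base = build_molecule(water_tmpl)
    quats = rng.normal(size=(len(placed), 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rots = _quat_to_matrix(quats)
    all_pos = np.einsum("nij,kj->nki", rots, base.positions) + placed[:, None, :]
    for pos in all_pos:
        w = base.copy()
        w.positions = pos
        fragments.append(w)

    return Configuration.from_fragments(box, fragments).wrap()


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices from unit quaternions, vectorized over the first axis."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
    ], axis=1)


def _orient_water(w: Fragment, ow: np.ndarray, hw: np.ndarray, rng) -> Fragment:
    """Rigidly place a water with its oxygen at ``ow`` and one H at ``hw``."""
    target_dir = (hw - ow) / np.linalg.norm(hw - ow)
    local_dir = (w.positions[1] - w.positions[0])
    local_dir /= np.linalg.norm(local_dir)
    axis = np.cross(local_dir, target_dir)
    if np.linalg.norm(axis) < 1e-12:
        R = np.eye(3)
    else:
        ang = np.degrees(np.arccos(np.clip(np.dot(local_dir, target_dir), -1, 1)))
        R = rotation_about_axis(axis, ang)
    spin = rotation_about_axis(target_dir, rng.uniform(0, 360.0))
    w.positions = (spin @ R @ (w.positions - w.positions[0]).T).T + ow
    return w


def generate_ensemble(params: GeneratorParams) -> Ensemble:
    """Generate ``params.n_configurations`` posed configurations (seeded)."""
    n_alpha, n_beta, n_water = plan_composition(
        params.n_solute, params.water_ratio, params.alpha_fraction)
    template = cellobiose_template()
    water_tmpl = water_template()
    n_solute_atoms = len(template.atoms)
    box = box_from_density(
        {"solute": n_alpha + n_beta, "water": n_water},
        {"solute": n_solute_atoms, "water": 3},
        params.number_density)
    root = np.random.default_rng(params.seed)
    seeds = root.integers(0, 2**31 - 1, size=params.n_configurations)
    configs = [
        _generate_configuration(params, box, n_alpha, n_beta, n_water,
                                template, water_tmpl, np.random.default_rng(int(s)))
        for s in seeds
    ]
    return Ensemble(configs)


def synthesize_target_fq(ensemble: Ensemble, schemes=None, noise_sd: float = 0.0,
                         Q: np.ndarray | None = None, seed: int = 0,
                         dr: float = 0.02) -> list:
    """Per-scheme total structure factors from an ensemble, plus optional
    i.i.d. Gaussian noise -- the synthetic stand-in for measured data."""
    from .analysis import compute_rdf  # avoid import cycle at module load

    schemes = default_schemes() if schemes is None else schemes
    if not schemes:
        raise ValueError("at least one isotopomer scheme is required")
    Q = scattering.default_q_grid() if Q is None else np.asarray(Q, float)
    cfg0 = ensemble.configurations[0]
    comp = cfg0.composition()
    classes = sorted(comp)
    r_max = 0.49 * min(ensemble.box.edge_lengths)
    partials = []
    for i, a in enumerate(classes):
        for b in classes[i:]:
            rdf = compute_rdf(ensemble, (a, b), dr=dr, r_max=r_max, mode="all")
            partials.append(scattering.sq_from_rdf(rdf, Q, window=True))
    table = ScatteringLengthTable.default()
    rng = np.random.default_rng(seed)
    out = []
    for scheme in schemes:
        b_map = scattering.effective_b_map(scheme, classes, table)
        total = scattering.total_fq(partials, comp, b_map, scheme=scheme.name)
        if noise_sd > 0:
            total = TotalStructureFactor(
                scheme.name, total.Q, total.F + rng.normal(0, noise_sd, size=len(Q)),
                total.composition, total.effective_b,
                meta={"noise_sd": noise_sd})
        out.append(total)
    return out
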