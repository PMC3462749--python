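"""Periodic molecular configurations, topology templates and molecule building.

The central objects are :class:`Configuration` (a periodic box of labeled atomic
sites) and :class:`Ensemble` (an ordered collection of configurations sharing one
composition).  Disaccharide and water instances are built from idealized internal
coordinates: a glucopyranose ring is an exact tetrahedral ``4C1`` chair (uniform
ring bonds, 109.47 deg angles, alternating +/-60 deg ring torsions, which closes
the six-ring identically), with substituents placed on the open tetrahedral
directions -- equatorial for heavy atoms and axial for ring hydrogens in the beta
anomer, inverted at C1 for alpha.  All O-H bonds are 1.0 angstrom.

Site labeling carries two levels: a coarse ``site_class`` used for scattering and
potential grouping (Cs, Hc, Oh, Ho, Oe, Ow, Hw) and a fine ``role`` naming the
chemical position (C1 ... O5, HO3, O4a/O4b, primed ring roles with a ``p``
suffix).  Hydroxyl and water hydrogens are flagged exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    measure_dihedral,
    minimum_image_displacement,
    nerf_place,
    rotation_about_axis,
    wrap_range,
)

__all__ = [
    "AtomSite",
    "SimulationBox",
    "Configuration",
    "Ensemble",
    "Fragment",
    "MoleculeTemplate",
    "cellobiose_template",
    "water_template",
    "build_molecule",
    "set_torsion",
    "measure_named_torsion",
    "SITE_CLASSES",
]

# Coarse site-class vocabulary: sugar carbon, carbon-bound H, hydroxyl O and H,
# ether (ring / glycosidic-linkage) O, water O and H.
SITE_CLASSES = ("Cs", "Hc", "Oh", "Ho", "Oe", "Ow", "Hw")

TETRA = 109.4712206  # exact tetrahedral angle, degrees
RING_BOND = 1.52     # uniform idealized ring bond, angstrom
C_O = 1.43
C_H = 1.09
O_H = 1.00
GLYCOSIDIC_ANGLE = 116.0  # C1'-O4-C4, degrees


@dataclass
class AtomSite:
    """A single labeled atomic site (view object; bulk storage is array-based)."""

    site_id: int
    element: str
    site_class: str
    exchangeable: bool
    position: np.ndarray
    molecule_id: int
    residue: str
    role: str = ""

    def __post_init__(self):
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site_class {self.site_class!r}")
        if self.exchangeable and not self.element.startswith(("H", "D")):
            raise ValueError("only hydrogen sites may be exchangeable")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite position")


@dataclass(frozen=True)
class SimulationBox:
    edge_lengths: tuple
    periodic: bool = True
    number_density: float | None = None  # atoms / A^3

    def __post_init__(self):
        edges = tuple(float(e) for e in np.atleast_1d(self.edge_lengths).ravel()[:3])
        if len(edges) == 1:
            edges = edges * 3
        object.__setattr__(self, "edge_lengths", edges)
        if any(e <= 0 for e in edges):
            raise ValueError("box edges must be positive")

    @property
    def volume(self) -> float:
        return float(np.prod(self.edge_lengths))

    def check_density(self, n_atoms: int, rtol: float = 1e-6) -> None:
        if self.number_density is None:
            return
        actual = n_atoms / self.volume
        if abs(actual - self.number_density) > rtol * self.number_density:
            raise ValueError(
                f"declared density {self.number_density} inconsistent with "
                f"{n_atoms} atoms in volume {self.volume:.3f} (actual {actual:.6g})"
            )


@dataclass
class Fragment:
    """A single molecule before insertion into a configuration.

    Arrays are indexed 0..n-1 locally; ``torsions`` maps torsion names to local
    index quadruples and ``restraints`` holds (i, j, target_A, tolerance_A).
    """

    name: str
    positions: np.ndarray
    elements: np.ndarray
    site_class: np.ndarray
    role: np.ndarray
    exchangeable: np.ndarray
    residue: np.ndarray
    bonds: list
    torsions: dict = field(default_factory=dict)
    restraints: list = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def index_of(self, role: str) -> int:
        hits = np.flatnonzero(self.role == role)
        if len(hits) != 1:
            raise KeyError(f"role {role!r} matches {len(hits)} atoms")
        return int(hits[0])

    def copy(self) -> "Fragment":
        return Fragment(
            self.name,
            self.positions.copy(),
            self.elements.copy(),
            self.site_class.copy(),
            self.role.copy(),
            self.exchangeable.copy(),
            self.residue.copy(),
            list(self.bonds),
            dict(self.torsions),
            list(self.restraints),
        )

    def bonded_distances(self):
        return {
            (i, j): float(np.linalg.norm(self.positions[i] - self.positions[j]))
            for i, j in self.bonds
        }


@dataclass
class MoleculeTemplate:
    """Topology + internal coordinates sufficient to build a 3D instance."""

    name: str
    atoms: list                      # (element, site_class, exchangeable)
    bonds: list
    torsions: dict
    restraints: list
    internal_coordinates: dict       # bond lengths/angles by kind

    def __post_init__(self):
        for (i, j, target, tol) in self.restraints:
            if target <= 0:
                raise ValueError("restraint distances must be positive")
        n = len(self.atoms)
        # bond graph must connect the molecule
        adj = {k: set() for k in range(n)}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen, stack = set(), [0]
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            stack.extend(adj[k] - seen)
        if len(seen) != n:
            raise ValueError("bond graph is not connected")


# ---------------------------------------------------------------------------
# glucopyranose unit construction
# ---------------------------------------------------------------------------

def _open_tetra_directions(center, n1, n2):
    """The two unoccupied tetrahedral directions at ``center`` with bonded
    neighbors at ``n1`` and ``n2``."""
    u1 = (n1 - center) / np.linalg.norm(n1 - center)
    u2 = (n2 - center) / np.linalg.norm(n2 - center)
    s = -(u1 + u2)
    s /= np.linalg.norm(s)
    t = np.cross(u1, u2)
    t /= np.linalg.norm(t)
    target = np.cos(np.radians(TETRA))
    alpha = target / float(np.dot(s, u1))
    beta = np.sqrt(max(0.0, 1.0 - alpha * alpha))
    return s * alpha + t * beta, s * alpha - t * beta


def _build_glucopyranose(kind: str, anomer: str, icoords: dict,
                         omega: float, hydroxyl_dihedrals: dict | None = None):
    """Build one glucopyranose unit in local coordinates.

    kind: 'reducing' (anomeric OH at C1; O4 is the bare linkage oxygen) or
    'non_reducing' (C1 carries the glycosidic attachment direction; O4 is a
    hydroxyl).  Returns (atoms, attach_dir) where atoms is a list of
    (role, element, site_class, exchangeable, position) and attach_dir is the
    unit vector of the glycosidic bond direction at C1 (non-reducing only).
    """
    hydroxyl_dihedrals = hydroxyl_dihedrals or {}
    b = icoords["ring_bond"]
    tau = icoords["ring_torsion"]
    ang = icoords["ring_angle"]

    # ring skeleton C1 C2 C3 C4 C5 O5 -- exact chair closure by symmetry
    C1 = np.zeros(3)
    C2 = np.array([b, 0.0, 0.0])
    C3 = C2 + b * np.array([-np.cos(np.radians(ang)), np.sin(np.radians(ang)), 0.0])
    C4 = nerf_place(C1, C2, C3, b, ang, tau)
    C5 = nerf_place(C2, C3, C4, b, ang, -tau)
    O5 = nerf_place(C3, C4, C5, b, ang, tau)
    ring = {"C1": C1, "C2": C2, "C3": C3, "C4": C4, "C5": C5, "O5": O5}
    order = ["C1", "C2", "C3", "C4", "C5", "O5"]
    ring_xyz = np.array([ring[k] for k in order])
    centroid = ring_xyz.mean(axis=0)
    # ring normal from SVD (smallest principal axis of the ring coordinates)
    _, _, vt = np.linalg.svd(ring_xyz - centroid)
    normal = vt[2]

    def open_dirs(role):
        i = order.index(role)
        prev_a = ring[order[i - 1]]
        next_a = ring[order[(i + 1) % 6]]
        d1, d2 = _open_tetra_directions(ring[role], prev_a, next_a)
        # axial = larger projection on the ring normal
        if abs(np.dot(d1, normal)) >= abs(np.dot(d2, normal)):
            return d1, d2  # axial, equatorial
        return d2, d1

    for key in ("C-O", "C-H", "O-H"):
        if key not in icoords:
            raise KeyError(f"missing internal coordinate {key!r}")
    c_o, c_h, o_h = icoords["C-O"], icoords["C-H"], icoords["O-H"]

    atoms = []  # (role, element, site_class, exch, pos)

    def add(role, element, site_class, exch, pos):
        atoms.append((role, element, site_class, exch, np.asarray(pos, float)))

    attach_dir = None
    # C1 substituents
    ax, eq = open_dirs("C1")
    if kind == "reducing":
        if anomer == "beta":
            o1_dir, h1_dir = eq, ax
        elif anomer == "alpha":
            o1_dir, h1_dir = ax, eq
        else:
            raise ValueError(f"unknown anomer {anomer!r}")
        O1 = C1 + c_o * o1_dir
        add("O1", "O", "Oh", False, O1)
        add("H1", "H", "Hc", False, C1 + c_h * h1_dir)
        dih = hydroxyl_dihedrals.get("HO1", 180.0)
        add("HO1", "H", "Ho", True, nerf_place(C2, C1, O1, o_h, icoords["C-O-H"], dih))
    else:
        # non-reducing: equatorial slot is the beta-glycosidic attachment
        attach_dir = eq
        add("H1", "H", "Hc", False, C1 + c_h * ax)

    # C2, C3 hydroxyls (and C4 hydroxyl on the non-reducing ring)
    hydroxyl_positions = ["C2", "C3"] + (["C4"] if kind == "non_reducing" else [])
    for cpos in hydroxyl_positions:
        i = order.index(cpos)
        ax, eq = open_dirs(cpos)
        Ox = ring[cpos] + c_o * eq
        n = cpos[1]
        add(f"O{n}", "O", "Oh", False, Ox)
        add(f"H{n}", "H", "Hc", False, ring[cpos] + c_h * ax)
        dih = hydroxyl_dihedrals.get(f"HO{n}", 180.0)
        prev_a = ring[order[i - 1]]
        add(f"HO{n}", "H", "Ho", True,
            nerf_place(prev_a, ring[cpos], Ox, o_h, icoords["C-O-H"], dih))

    if kind == "reducing":
        # bare glycosidic oxygen at C4 (class Oe); H4 axial
        ax, eq = open_dirs("C4")
        add("O4", "O", "Oe", False, C4 + c_o * eq)
        add("H4", "H", "Hc", False, C4 + c_h * ax)

    # C5: equatorial C6 exocyclic carbon, axial H5
    ax, eq = open_dirs("C5")
    C6 = C5 + icoords["C-C"] * eq
    add("C6", "C", "Cs", False, C6)
    add("H5", "H", "Hc", False, C5 + c_h * ax)
    # hydroxymethyl group: omega = O5-C5-C6-O6
    O6 = nerf_place(O5, C5, C6, c_o, TETRA, omega)
    add("O6", "O", "Oh", False, O6)
    add("H6R", "H", "Hc", False, nerf_place(O5, C5, C6, c_h, TETRA, omega + 120.0))
    add("H6S", "H", "Hc", False, nerf_place(O5, C5, C6, c_h, TETRA, omega - 120.0))
    dih = hydroxyl_dihedrals.get("HO6", 180.0)
    add("HO6", "H", "Ho", True, nerf_place(C5, C6, O6, o_h, icoords["C-O-H"], dih))

    for role in order:
        el = "O" if role == "O5" else "C"
        cls = "Oe" if role == "O5" else "Cs"
        add(role, el, cls, False, ring[role])

    return atoms, attach_dir


_RING_BONDS = [("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"),
               ("C5", "O5"), ("O5", "C1")]


def _unit_bonds(kind: str):
    bonds = list(_RING_BONDS)
    bonds += [("C1", "H1"), ("C2", "H2"), ("C2", "O2"), ("O2", "HO2"),
              ("C3", "H3"), ("C3", "O3"), ("O3", "HO3"),
              ("C4", "H4"), ("C4", "O4"),
              ("C5", "H5"), ("C5", "C6"),
              ("C6", "H6R"), ("C6", "H6S"), ("C6", "O6"), ("O6", "HO6")]
    if kind == "reducing":
        bonds += [("C1", "O1"), ("O1", "HO1")]
    else:
        bonds += [("O4", "HO4")]
    return bonds


DEFAULT_TORSIONS = {"phi_H": 22.0, "psi_H": -40.0, "omega": 65.0, "omega_p": 65.0}

_DEFAULT_ICOORDS = {
    "ring_bond": RING_BOND,
    "ring_angle": TETRA,
    "ring_torsion": -60.0,  # sign fixes the D-sugar ring chirality
    "C-C": RING_BOND,
    "C-O": C_O,
    "C-H": C_H,
    "O-H": O_H,
    "C-O-H": 107.0,
    "glycosidic_bond": C_O,
    "glycosidic_angle": GLYCOSIDIC_ANGLE,
}


def _assemble_cellobiose(anomer: str, torsions: dict, icoords: dict,
                         hydroxyl_dihedrals: dict | None = None) -> Fragment:
    t = dict(DEFAULT_TORSIONS)
    t.update(torsions or {})
    red_atoms, _ = _build_glucopyranose("reducing", anomer, icoords,
                                        omega=t["omega"],
                                        hydroxyl_dihedrals=hydroxyl_dihedrals)
    nr_atoms, attach = _build_glucopyranose("non_reducing", "beta", icoords,
                                            omega=t["omega_p"],
                                            hydroxyl_dihedrals=hydroxyl_dihedrals)

    red = {r: p for (r, _, _, _, p) in red_atoms}
    # place the primed anomeric carbon: angle C1'-O4-C4, dihedral psi = C1'-O4-C4-H4
    C1p_target = nerf_place(red["H4"], red["C4"], red["O4"],
                            icoords["glycosidic_bond"], icoords["glycosidic_angle"],
                            t["psi_H"])
    # rigid-transform the non-reducing unit: C1 -> C1p_target with its
    # attachment direction pointing at O4
    u_target = red["O4"] - C1p_target
    u_target /= np.linalg.norm(u_target)
    axis = np.cross(attach, u_target)
    if np.linalg.norm(axis) < 1e-12:
        R = np.eye(3) if np.dot(attach, u_target) > 0 else rotation_about_axis(
            np.array([1.0, 0.0, 0.0]) if abs(attach[0]) < 0.9 else np.array([0.0, 1.0, 0.0]),
            180.0)
    else:
        ang = np.degrees(np.arccos(np.clip(np.dot(attach, u_target), -1, 1)))
        R = rotation_about_axis(axis, ang)
    nr_local_C1 = next(p for (r, _, _, _, p) in nr_atoms if r == "C1")
    nr_placed = [(r, e, c, x, R @ (p - nr_local_C1) + C1p_target)
                 for (r, e, c, x, p) in nr_atoms]
    # set phi = H1'-C1'-O4-C4 by rotating the primed unit about the C1'-O4 axis
    H1p = next(p for (r, _, _, _, p) in nr_placed if r == "H1")
    current_phi = measure_dihedral(H1p, C1p_target, red["O4"], red["C4"])
    bond_axis = C1p_target - red["O4"]
    delta = wrap_range(t["phi_H"] - current_phi)
    Rphi = rotation_about_axis(bond_axis, delta)
    test = Rphi @ (H1p - C1p_target) + C1p_target
    if abs(wrap_range(measure_dihedral(test, C1p_target, red["O4"], red["C4"]) - t["phi_H"])) > 1e-6:
        Rphi = rotation_about_axis(bond_axis, -delta)
    nr_placed = [(r, e, c, x, Rphi @ (p - C1p_target) + C1p_target)
                 for (r, e, c, x, p) in nr_placed]

    # merge; primed roles get a 'p' suffix, O4 keeps anomer-specific labeling
    roles, elements, classes, exch, residues, positions = [], [], [], [], [], []
    index = {}
    o4_role = "O4a" if anomer == "alpha" else "O4b"
    for (r, e, c, x, p) in red_atoms:
        role = o4_role if r == "O4" else r
        index[role] = len(roles)
        roles.append(role)
        elements.append(e)
        classes.append(c)
        exch.append(x)
        residues.append("reducing")
        positions.append(p)
    for (r, e, c, x, p) in nr_placed:
        role = r + "p"
        index[role] = len(roles)
        roles.append(role)
        elements.append(e)
        classes.append(c)
        exch.append(x)
        residues.append("non_reducing")
        positions.append(p)

    bonds = []
    for (a, bb) in _unit_bonds("reducing"):
        aa = o4_role if a == "O4" else a
        bb2 = o4_role if bb == "O4" else bb
        bonds.append((index[aa], index[bb2]))
    for (a, bb) in _unit_bonds("non_reducing"):
        bonds.append((index[a + "p"], index[bb + "p"]))
    bonds.append((index[o4_role], index["C1p"]))

    torsion_map = {
        "phi_H": (index["H1p"], index["C1p"], index[o4_role], index["C4"]),
        "psi_H": (index["C1p"], index[o4_role], index["C4"], index["H4"]),
        "omega": (index["O5"], index["C5"], index["C6"], index["O6"]),
        "omega_p": (index["O5p"], index["C5p"], index["C6p"], index["O6p"]),
        "chi3": (index["HO3"], index["O3"], index["C3"], index["C2"]),
    }

    pos_arr = np.array(positions)

    def dist(a, b):
        return float(np.linalg.norm(pos_arr[index[a]] - pos_arr[index[b]]))

    restraints = [(index["H1p"], index["H4"], 2.205, 0.3)]
    for suffix in ("", "p"):
        for (a, b) in (("C1", "C4"), ("C2", "C5"), ("C3", "O5")):
            aa = (o4_role if a + suffix == "O4" else a + suffix)
            bb = b + suffix
            restraints.append((index[aa], index[bb], dist(aa, bb), 0.2))

    return Fragment(
        name=f"cellobiose_{anomer}",
        positions=pos_arr,
        elements=np.array(elements, dtype="U2"),
        site_class=np.array(classes, dtype="U2"),
        role=np.array(roles, dtype="U4"),
        exchangeable=np.array(exch, dtype=bool),
        residue=np.array(residues, dtype="U12"),
        bonds=bonds,
        torsions=torsion_map,
        restraints=restraints,
    )


def cellobiose_template(icoords: dict | None = None) -> MoleculeTemplate:
    """Topology template for cellobiose (C12H22O11, 45 atoms)."""
    ic = dict(_DEFAULT_ICOORDS)
    if icoords:
        ic.update(icoords)
    frag = _assemble_cellobiose("beta", {}, ic)
    atoms = [(e, c, bool(x)) for e, c, x in
             zip(frag.elements, frag.site_class, frag.exchangeable)]
    return MoleculeTemplate(
        name="cellobiose",
        atoms=atoms,
        bonds=frag.bonds,
        torsions=frag.torsions,
        restraints=frag.restraints,
        internal_coordinates=ic,
    )


def water_template() -> MoleculeTemplate:
    return MoleculeTemplate(
        name="water",
        atoms=[("O", "Ow", False), ("H", "Hw", True), ("H", "Hw", True)],
        bonds=[(0, 1), (0, 2)],
        torsions={},
        restraints=[],
        internal_coordinates={"O-H": O_H, "H-O-H": TETRA},
    )


def build_molecule(template: MoleculeTemplate, anomer: str = "beta",
                   torsions: dict | None = None,
                   hydroxyl_dihedrals: dict | None = None) -> Fragment:
    """Build a 3D molecule instance from a template's internal coordinates.

    For the disaccharide template, ``anomer`` selects alpha/beta (the C1
    substituent geometry is inverted for alpha) and ``torsions`` may override
    the named defaults (phi_H, psi_H, omega, omega_p), degrees.
    """
    ic = template.internal_coordinates
    if template.name == "cellobiose":
        return _assemble_cellobiose(anomer, torsions or {}, ic, hydroxyl_dihedrals)
    if template.name == "water":
        if "O-H" not in ic:
            raise KeyError("missing internal coordinate 'O-H' for atom Hw")
        oh = ic["O-H"]
        half = np.radians(ic["H-O-H"] / 2.0)
        pos = np.array([
            [0.0, 0.0, 0.0],
            [oh * np.sin(half), 0.0, oh * np.cos(half)],
            [-oh * np.sin(half), 0.0, oh * np.cos(half)],
        ])
        return Fragment(
            name="water",
            positions=pos,
            elements=np.array(["O", "H", "H"], dtype="U2"),
            site_class=np.array(["Ow", "Hw", "Hw"], dtype="U2"),
            role=np.array(["Ow", "Hw1", "Hw2"], dtype="U4"),
            exchangeable=np.array([False, True, True]),
            residue=np.array(["water"] * 3, dtype="U12"),
            bonds=[(0, 1), (0, 2)],
        )
    raise ValueError(f"unknown template {template.name!r}")


def _distal_atoms(fragment: Fragment, j: int, k: int) -> set:
    """Atoms on the k-side of bond (j, k) in the fragment's bond graph."""
    adj = {}
    for a, b in fragment.bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen, stack = {j, k}, [k]
    out = {k}
    while stack:
        cur = stack.pop()
        for nb in adj.get(cur, ()):
            if nb not in seen:
                seen.add(nb)
                out.add(nb)
                stack.append(nb)
    return out


def set_torsion(fragment: Fragment, name_or_quad, angle_deg: float) -> None:
    """Rotate the distal side of a torsion's central bond to the target angle."""
    quad = fragment.torsions[name_or_quad] if isinstance(name_or_quad, str) else name_or_quad
    i, j, k, l = quad
    pos = fragment.positions
    current = measure_dihedral(pos[i], pos[j], pos[k], pos[l])
    delta = wrap_range(angle_deg - current)
    axis = pos[k] - pos[j]
    moving = sorted(_distal_atoms(fragment, j, k))
    for sign in (1.0, -1.0):
        R = rotation_about_axis(axis, sign * delta)
        trial = pos.copy()
        trial[moving] = (R @ (pos[moving] - pos[k]).T).T + pos[k]
        got = measure_dihedral(trial[i], trial[j], trial[k], trial[l])
        if abs(wrap_range(got - angle_deg)) < 1e-6:
            fragment.positions = trial
            return
    raise RuntimeError("torsion rotation failed to converge")


def measure_named_torsion(fragment: Fragment, name: str) -> float:
    i, j, k, l = fragment.torsions[name]
    p = fragment.positions
    return measure_dihedral(p[i], p[j], p[k], p[l])


# ---------------------------------------------------------------------------
# configurations and ensembles
# ---------------------------------------------------------------------------

@dataclass
class Configuration:
    """A periodic box of labeled atomic sites (array-of-structures storage)."""

    box: SimulationBox
    positions: np.ndarray
    elements: np.ndarray
    site_class: np.ndarray
    role: np.ndarray
    exchangeable: np.ndarray
    molecule_id: np.ndarray
    residue: np.ndarray
    bonds: list = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def sites(self):
        return [
            AtomSite(i, self.elements[i], self.site_class[i],
                     bool(self.exchangeable[i]), self.positions[i],
                     int(self.molecule_id[i]), self.residue[i], self.role[i])
            for i in range(self.n_atoms)
        ]

    def select(self, site_class=None, role=None, residue=None, element=None) -> np.ndarray:
        """Indices of sites matching all given labels (each may be a str or set)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        for arr, want in ((self.site_class, site_class), (self.role, role),
                          (self.residue, residue), (self.elements, element)):
            if want is None:
                continue
            wants = {want} if isinstance(want, str) else set(want)
            mask &= np.isin(arr, sorted(wants))
        return np.flatnonzero(mask)

    def composition(self) -> dict:
        """Number fraction of each site class."""
        classes, counts = np.unique(self.site_class, return_counts=True)
        return {c: n / self.n_atoms for c, n in zip(classes, counts)}

    def wrap(self) -> "Configuration":
        """Wrap molecules into the box as rigid units (by molecule centroid)."""
        if not self.box.periodic:
            return self
        edges = np.asarray(self.box.edge_lengths)
        pos = self.positions.copy()
        for mid in np.unique(self.molecule_id):
            idx = np.flatnonzero(self.molecule_id == mid)
            centroid = pos[idx].mean(axis=0)
            shift = np.floor(centroid / edges) * edges
            pos[idx] -= shift
        return replace(self, positions=pos)

    @staticmethod
    def from_fragments(box: SimulationBox, fragments) -> "Configuration":
        parts = {k: [] for k in ("positions", "elements", "site_class", "role",
                                 "exchangeable", "residue")}
        molecule_id, bonds = [], []
        offset = 0
        for mid, frag in enumerate(fragments):
            parts["positions"].append(frag.positions)
            parts["elements"].append(frag.elements)
            parts["site_class"].append(frag.site_class)
            parts["role"].append(frag.role)
            parts["exchangeable"].append(frag.exchangeable)
            parts["residue"].append(frag.residue)
            molecule_id.extend([mid] * frag.n_atoms)
            bonds.extend((i + offset, j + offset) for i, j in frag.bonds)
            offset += frag.n_atoms
        return Configuration(
            box=box,
            positions=np.concatenate(parts["positions"]),
            elements=np.concatenate(parts["elements"]),
            site_class=np.concatenate(parts["site_class"]),
            role=np.concatenate(parts["role"]),
            exchangeable=np.concatenate(parts["exchangeable"]),
            molecule_id=np.array(molecule_id, dtype=int),
            residue=np.concatenate(parts["residue"]),
            bonds=bonds,
        )


@dataclass
class Ensemble:
    configurations: list
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            if len(self.weights) != len(self.configurations):
                raise ValueError("one weight per configuration")
        if self.configurations:
            ref = self.configurations[0]
            for c in self.configurations[1:]:
                if c.n_atoms != ref.n_atoms or not np.array_equal(c.site_class, ref.site_class):
                    raise ValueError("configurations must share composition and labeling")

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def box(self) -> SimulationBox:
        return self.configurations[0].box
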