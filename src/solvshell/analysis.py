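"""Ensemble structure analysis: RDFs, coordination numbers, torsion statistics,
hydroxymethyl rotamer populations and spatial density functions.

Coordination numbers are computed two ways -- quadrature of the RDF
(n = 4 pi rho c_beta \\int g r^2 dr) and direct neighbor counting -- and the two
must agree within binning error; both are exposed.  Torsion statistics use
circular-aware windows with the two reduction rules used for distribution
summaries: the mean of the two tallest histogram bins ("peak average") and a
nonlinear Gaussian fit of the windowed histogram.  Spatial density functions
accumulate target positions in a per-molecule local frame, either as a direct
3D histogram (used for projections and enclosed-fraction iso-levels) or as a
spherical-harmonic expansion of the angular density over a radial shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .ensemble import SITE_CLASSES, Configuration, Ensemble
from .geometry import measure_dihedral, minimum_image_displacement, wrap_range
from .scattering import Rdf

__all__ = [
    "CoordinationResult",
    "TorsionDistribution",
    "RotamerPopulations",
    "LocalFrame",
    "SdfGrid",
    "compute_rdf",
    "coordination_number",
    "direct_coordination",
    "find_first_minimum",
    "find_first_maximum",
    "collect_torsions",
    "torsion_statistics",
    "classify_rotamer",
    "rotamer_populations_from_samples",
    "average_rdfs",
    "compute_sdf",
    "iso_level_for_fraction",
    "enclosed_fraction",
    "enclosed_mass_at_fraction",
    "project_sdf",
    "TORSION_ROLES",
]

ROTAMER_REFS = {"gt": 65.0, "gg": -65.0, "tg": 180.0}

# role quadruples of the named torsions (primed roles = non-reducing ring)
TORSION_ROLES = {
    "phi_H": ("H1p", "C1p", ("O4a", "O4b"), "C4"),
    "psi_H": ("C1p", ("O4a", "O4b"), "C4", "H4"),
    "omega": ("O5", "C5", "C6", "O6"),
    "omega_p": ("O5p", "C5p", "C6p", "O6p"),
}


def _resolve_selection(config: Configuration, label) -> np.ndarray:
    """Indices for a site_class name, a role name, or an iterable of either."""
    if isinstance(label, (list, tuple, set, frozenset)) and not isinstance(label, str):
        idx = np.concatenate([_resolve_selection(config, l) for l in label])
        return np.unique(idx)
    if isinstance(label, np.ndarray):
        return label
    if label in SITE_CLASSES:
        idx = config.select(site_class=label)
    else:
        idx = config.select(role=label)
    if len(idx) == 0:
        raise ValueError(f"empty selection for {label!r}")
    return idx


def _pair_counts(config: Configuration, ia: np.ndarray, ib: np.ndarray,
                 edges: np.ndarray, mode: str) -> np.ndarray:
    """Histogram of minimum-image a-b pair distances by radial bin.

    mode: 'inter' excludes same-molecule pairs, 'intra' keeps only them,
    'all' counts every distinct pair.  Pairs are counted once per (a-site,
    b-site) ordered occurrence, matching the per-alpha-site normalization.
    Bins are right-inclusive, (edges[i], edges[i+1]]; one sparse-distance
    pipeline serves all modes so the conventions cannot drift apart.
    """
    if mode not in ("all", "inter", "intra"):
        raise ValueError(f"unknown mode {mode!r}")
    box_edges = np.asarray(config.box.edge_lengths)
    pos = config.positions - np.floor(config.positions / box_edges) * box_edges
    tree_a = cKDTree(pos[ia], boxsize=box_edges)
    tree_b = cKDTree(pos[ib], boxsize=box_edges)
    sparse = tree_a.sparse_distance_matrix(tree_b, max_distance=float(edges[-1]),
                                           output_type="ndarray")
    d = sparse["v"]
    keep = d > 1e-9  # drop self pairs from overlapping selections
    if mode != "all":
        same = (config.molecule_id[ia[sparse["i"]]]
                == config.molecule_id[ib[sparse["j"]]])
        keep &= same if mode == "intra" else ~same
    d = d[keep]
    idx = np.searchsorted(edges, d, side="left") - 1
    valid = (idx >= 0) & (d > edges[0])
    counts = np.zeros(len(edges) - 1)
    np.add.at(counts, idx[valid], 1.0)
    return counts


def compute_rdf(ensemble: Ensemble, pair, dr: float = 0.02,
                r_max: float | None = None, mode: str = "inter") -> Rdf:
    """Radial distribution function between two labeled selections.

    ``pair`` names two selections by site class or role.  Normalization is the
    ideal-gas shell expectation per alpha site per configuration, using exact
    shell volumes; ``c_beta`` is the partner selection's number fraction so
    that coordination integrals count absolute neighbors.
    """
    configs = ensemble.configurations
    box = ensemble.box
    half = 0.5 * min(box.edge_lengths)
    if r_max is None:
        r_max = half
    if r_max > half + 1e-9:
        raise ValueError("r_max exceeds half the smallest box edge")
    edges = np.arange(0.0, r_max + 0.5 * dr, dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))
    n_a = n_b = 0
    for cfg in configs:
        ia = _resolve_selection(cfg, pair[0])
        ib = _resolve_selection(cfg, pair[1])
        n_a, n_b = len(ia), len(ib)
        counts += _pair_counts(cfg, ia, ib, edges, mode)
    rho = configs[0].n_atoms / box.volume
    c_beta = n_b / configs[0].n_atoms
    shell_volumes = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = len(configs) * n_a * shell_volumes * rho * c_beta
    g = counts / expected
    return Rdf(tuple(pair), centers, g, rho, c_beta,
               meta={"mode": mode, "n_alpha": n_a, "n_beta": n_b,
                     "n_configurations": len(configs), "dr": dr})


@dataclass
class CoordinationResult:
    pair: tuple
    r1: float
    r2: float
    n_bar: float
    method: str  # 'rdf_integral' or 'direct_count'

    def __post_init__(self):
        if self.n_bar < -1e-12:
            raise ValueError("coordination number must be non-negative")


def coordination_number(rdf: Rdf, r1: float, r2: float) -> CoordinationResult:
    """Average neighbor count by quadrature: n = 4 pi rho c_beta \\int g r^2 dr."""
    if r1 >= r2:
        raise ValueError("require r1 < r2")
    if r1 < rdf.r[0] - rdf.meta.get("dr", 0.02) or r2 > rdf.r[-1] + rdf.meta.get("dr", 0.02):
        raise ValueError("integration range outside the RDF grid")
    inner = rdf.r[(rdf.r > r1) & (rdf.r < r2)]
    r = np.concatenate([[r1], inner, [r2]])  # include exact shell bounds
    g = np.interp(r, rdf.r, rdf.g)
    n = 4.0 * np.pi * rdf.rho * rdf.c_beta * np.trapezoid(g * r**2, r)
    return CoordinationResult(rdf.pair, r1, r2, float(n), "rdf_integral")


def direct_coordination(ensemble: Ensemble, pair, r1: float, r2: float,
                        mode: str = "inter") -> CoordinationResult:
    """Average neighbor count by direct minimum-image counting (the oracle route)."""
    edges = np.array([r1, r2])
    total = 0.0
    n_a = 0
    for cfg in ensemble.configurations:
        ia = _resolve_selection(cfg, pair[0])
        ib = _resolve_selection(cfg, pair[1])
        n_a = len(ia)
        total += _pair_counts(cfg, ia, ib, edges, mode)[0]
    n_bar = total / (len(ensemble.configurations) * n_a)
    return CoordinationResult(tuple(pair), r1, r2, float(n_bar), "direct_count")


def find_first_maximum(rdf: Rdf, peak_threshold: float = 1.2,
                       smooth_bins: int = 3, window: tuple | None = None,
                       interpolate: bool = False):
    """Position of the first local maximum exceeding ``peak_threshold``.

    Smoothing and return conventions match :func:`find_first_minimum`;
    ``window`` optionally restricts the search range (angstrom) and
    ``interpolate`` refines the apex to sub-bin resolution with a three-point
    parabola.
    """
    kernel = np.ones(smooth_bins) / smooth_bins
    g = np.convolve(rdf.g, kernel, mode="same")
    lo, hi = window if window else (rdf.r[0], rdf.r[-1])
    for i in range(1, len(g) - 1):
        if not (lo <= rdf.r[i] <= hi):
            continue
        if g[i] > peak_threshold and g[i] >= g[i - 1] and g[i] >= g[i + 1]:
            if interpolate:
                denom = g[i - 1] - 2 * g[i] + g[i + 1]
                if denom < -1e-12:
                    shift = 0.5 * (g[i - 1] - g[i + 1]) / denom
                    dr = rdf.r[1] - rdf.r[0]
                    return float(rdf.r[i] + np.clip(shift, -1, 1) * dr)
            return float(rdf.r[i])
    return None


def find_first_minimum(rdf: Rdf, peak_threshold: float = 1.2,
                       smooth_bins: int = 3):
    """Position of the first local minimum after the first qualifying maximum.

    The curve is smoothed with a ``smooth_bins`` moving average first.  Returns
    the radius in angstrom, or ``None`` when no peak exceeds ``peak_threshold``
    (an explicit not-found result, e.g. for monotone curves).
    """
    kernel = np.ones(smooth_bins) / smooth_bins
    g = np.convolve(rdf.g, kernel, mode="same")
    i_peak = None
    for i in range(1, len(g) - 1):
        if g[i] > peak_threshold and g[i] >= g[i - 1] and g[i] >= g[i + 1]:
            i_peak = i
            break
    if i_peak is None:
        return None
    for i in range(i_peak + 1, len(g) - 1):
        if g[i] <= g[i - 1] and g[i] < g[i + 1]:
            return float(rdf.r[i])
    return None


# ---------------------------------------------------------------------------
# torsions and rotamers
# ---------------------------------------------------------------------------

def collect_torsions(ensemble: Ensemble, name: str, anomer: str | None = None) -> np.ndarray:
    """Per-solute-molecule torsion samples (degrees) across an ensemble.

    ``anomer`` may be 'alpha' or 'beta' to restrict by the O4a/O4b labeling.
    """
    roles = TORSION_ROLES[name]
    out = []
    for cfg in ensemble.configurations:
        solute_atoms = np.flatnonzero(cfg.residue != "water")
        for mid in np.unique(cfg.molecule_id[solute_atoms]):
            members = np.flatnonzero(cfg.molecule_id == mid)
            rmap = {r: i for i, r in zip(members, cfg.role[members])}
            if anomer == "alpha" and "O4a" not in rmap:
                continue
            if anomer == "beta" and "O4b" not in rmap:
                continue
            try:
                quad = [rmap[r] if isinstance(r, str)
                        else rmap[next(rr for rr in r if rr in rmap)]
                        for r in roles]
            except (KeyError, StopIteration):
                continue
            p = cfg.positions
            out.append(measure_dihedral(p[quad[0]], p[quad[1]], p[quad[2]], p[quad[3]]))
    return np.asarray(out)


@dataclass
class TorsionDistribution:
    name: str
    samples: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    peak_mean: float
    gaussian_mean: float
    gaussian_sigma: float
    window: tuple

    def __post_init__(self):
        if int(self.counts.sum()) != len(self.samples):
            raise ValueError("histogram counts must sum to the sample count")


def torsion_statistics(samples_or_ensemble, name: str, window: tuple,
                       bin_width: float = 2.0) -> TorsionDistribution:
    """Windowed circular torsion statistics with dual averaging.

    ``peak_mean`` averages the centers of the two tallest in-window bins;
    ``gaussian_mean`` is the center of a nonlinear least-squares Gaussian fit
    to the in-window histogram.  The window is treated circularly: samples are
    re-centered on the window midpoint before binning, so modes straddling
    +/-180 are handled.
    """
    if isinstance(samples_or_ensemble, Ensemble):
        samples = collect_torsions(samples_or_ensemble, name)
    else:
        samples = np.asarray(samples_or_ensemble, dtype=float)
    lo, hi = window
    if not (hi > lo):
        raise ValueError("empty window")
    mid = 0.5 * (lo + hi)
    rel = np.asarray([wrap_range(s - mid) for s in np.atleast_1d(samples)])
    edges = np.arange(-180.0, 180.0 + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(rel, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    in_win = (centers >= lo - mid) & (centers <= hi - mid)
    wc, wcounts = centers[in_win], counts[in_win]
    if wcounts.sum() == 0:
        raise ValueError("no samples inside the window")
    occupied = np.flatnonzero(wcounts > 0)
    top2 = occupied[np.argsort(wcounts[occupied])[-2:]]
    peak_mean = wrap_range(float(np.mean(wc[top2])) + mid)
    # Gaussian fit of the windowed histogram
    mu0 = float(np.sum(wc * wcounts) / wcounts.sum())
    sig0 = max(bin_width, float(np.sqrt(np.sum(wcounts * (wc - mu0) ** 2) / wcounts.sum())))
    amp0 = float(wcounts.max())

    def gauss(x, a, mu, sig):
        return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    try:
        popt, _ = curve_fit(gauss, wc, wcounts, p0=(amp0, mu0, sig0), maxfev=5000)
        g_mu, g_sig = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        g_mu, g_sig = mu0, sig0
    return TorsionDistribution(name, samples, edges, counts,
                               peak_mean, wrap_range(g_mu + mid), g_sig,
                               (lo, hi))


@dataclass
class RotamerPopulations:
    P_gt: float
    P_gg: float
    P_tg: float
    clamped: bool = False

    def __post_init__(self):
        total = self.P_gt + self.P_gg + self.P_tg
        if abs(total - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")
        for p in (self.P_gt, self.P_gg, self.P_tg):
            if not (-1e-12 <= p <= 1.0 + 1e-12):
                raise ValueError("populations must lie in [0, 1]")

    def as_tuple(self):
        return (self.P_gt, self.P_gg, self.P_tg)


def classify_rotamer(omega_deg: float) -> str:
    """Nearest staggered hydroxymethyl rotamer (gt +65, gg -65, tg 180 deg).

    Ties break toward the reference of smaller magnitude (gt before gg before
    tg), so 0 deg classifies as gt and +/-122.5 deg stay gauche.
    """
    w = wrap_range(omega_deg)
    best, best_d = None, None
    for label in ("gt", "gg", "tg"):  # tie-break order
        d = abs(wrap_range(w - ROTAMER_REFS[label]))
        if best_d is None or d < best_d - 1e-12:
            best, best_d = label, d
    return best


def rotamer_populations_from_samples(omega_samples) -> RotamerPopulations:
    labels = [classify_rotamer(w) for w in np.atleast_1d(omega_samples)]
    n = len(labels)
    return RotamerPopulations(labels.count("gt") / n, labels.count("gg") / n,
                              labels.count("tg") / n)


def average_rdfs(rdfs, weights) -> Rdf:
    """Weighted average of RDFs on a shared grid (e.g. 40:60 alpha:beta)."""
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    ref = rdfs[0]
    g = sum(w * r.g for w, r in zip(weights, rdfs))
    c_beta = float(sum(w * r.c_beta for w, r in zip(weights, rdfs)))
    return Rdf(ref.pair, ref.r, g, ref.rho, c_beta, meta={"averaged": True})


# ---------------------------------------------------------------------------
# spatial density functions
# ---------------------------------------------------------------------------

@dataclass
class LocalFrame:
    """Molecule-fixed frame anchored on a C-O-C fragment.

    x runs along the bisector of the C-O-C angle (pointing away from the two
    carbons), z along the C-O-C plane normal with its sign chosen so the
    orient atom (by default the ring hydroxymethyl carbon) sits at positive z.
    """

    origin_role: str = "O5p"
    ref_roles: tuple = ("C1p", "C5p")
    orient_role: str = "C6p"

    def axes(self, origin, ref1, ref2, orient):
        u1 = ref1 - origin
        u2 = ref2 - origin
        n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
        if n1 < 1e-9 or n2 < 1e-9:
            raise ValueError("degenerate frame: coincident atoms")
        u1, u2 = u1 / n1, u2 / n2
        z = np.cross(u1, u2)
        nz = np.linalg.norm(z)
        if nz < 1e-9:
            raise ValueError("degenerate frame: collinear C-O-C atoms")
        z /= nz
        x = -(u1 + u2)
        x /= np.linalg.norm(x)
        if np.dot(z, orient - origin) < 0:
            z = -z
        y = np.cross(z, x)
        return np.vstack([x, y, z])


@dataclass
class SdfGrid:
    frame: LocalFrame
    r_min: float
    r_max: float
    hist: np.ndarray          # normalized 3D probability histogram
    edges: np.ndarray         # shared Cartesian bin edges for all three axes
    angular: np.ndarray       # direct angular histogram density (ntheta, nphi)
    angular_sh: np.ndarray    # spherical-harmonic reconstruction on same grid
    theta: np.ndarray
    phi: np.ndarray
    l_max: int
    n_samples: int
    n_frames: int = 0         # molecule-frames accumulated (for absolute scale)

    def __post_init__(self):
        if self.n_samples and abs(self.hist.sum() - 1.0) > 1e-6:
            raise ValueError("3D histogram must be normalized")
        if np.any(self.hist < 0):
            raise ValueError("density must be non-negative")

    @property
    def per_frame_hist(self) -> np.ndarray:
        """Average target count per molecule-frame per voxel.

        Unlike the probability-normalized ``hist``, this scale is comparable
        between SDFs of different targets or origins (more neighbors = more
        intensity), which is what side-by-side projection maps need.
        """
        if self.n_frames == 0:
            return self.hist
        return self.hist * (self.n_samples / self.n_frames)


def _local_samples(ensemble: Ensemble, frame: LocalFrame, target,
                   r_min: float, r_max: float, same_molecule: bool | None):
    """Target displacements expressed in each solute's local frame.

    same_molecule: True restricts targets to the frame molecule (intramolecular
    SDFs such as the hydroxyl-proton cloud), False to other molecules (solvent
    SDFs), None keeps both.
    """
    out = []
    n_frames = 0
    for cfg in ensemble.configurations:
        box_edges = np.asarray(cfg.box.edge_lengths)
        it = _resolve_selection(cfg, target)
        solute_atoms = np.flatnonzero(cfg.residue != "water")
        for mid in np.unique(cfg.molecule_id[solute_atoms]):
            members = np.flatnonzero(cfg.molecule_id == mid)
            rmap = {r: i for i, r in zip(members, cfg.role[members])}
            needed = (frame.origin_role, *frame.ref_roles, frame.orient_role)
            if any(r not in rmap for r in needed):
                raise ValueError(f"frame atoms {needed} absent from molecule {mid}")
            p = cfg.positions
            origin = p[rmap[frame.origin_role]]
            axes = frame.axes(origin, p[rmap[frame.ref_roles[0]]],
                              p[rmap[frame.ref_roles[1]]], p[rmap[frame.orient_role]])
            n_frames += 1
            sel = it
            if same_molecule is True:
                sel = it[cfg.molecule_id[it] == mid]
            elif same_molecule is False:
                sel = it[cfg.molecule_id[it] != mid]
            if len(sel) == 0:
                continue
            disp = minimum_image_displacement(origin, p[sel], box_edges)
            d = np.linalg.norm(disp, axis=1)
            keep = (d >= r_min) & (d <= r_max)
            if keep.any():
                out.append(disp[keep] @ axes.T)
    return (np.concatenate(out) if out else np.empty((0, 3))), n_frames


def compute_sdf(ensemble: Ensemble, frame: LocalFrame, target,
                r_min: float = 0.0, r_max: float = 3.0, l_max: int = 8,
                n_theta: int = 32, n_phi: int = 64, n_grid: int = 24,
                same_molecule: bool | None = False) -> SdfGrid:
    """Spatial density function of ``target`` sites in the molecular frame."""
    local, n_frames = _local_samples(ensemble, frame, target, r_min, r_max,
                                     same_molecule)
    edges = np.linspace(-r_max, r_max, n_grid + 1)
    hist, _ = np.histogramdd(local, bins=(edges, edges, edges))
    total = hist.sum()
    if total > 0:
        hist = hist / total
    # angular density over the shell
    d = np.linalg.norm(local, axis=1)
    with np.errstate(invalid="ignore"):
        theta_s = np.arccos(np.clip(local[:, 2] / np.where(d > 0, d, 1.0), -1, 1))
    phi_s = np.mod(np.arctan2(local[:, 1], local[:, 0]), 2 * np.pi)
    t_edges = np.linspace(0, np.pi, n_theta + 1)
    p_edges = np.linspace(0, 2 * np.pi, n_phi + 1)
    ang_counts, _, _ = np.histogram2d(theta_s, phi_s, bins=(t_edges, p_edges))
    t_cent = 0.5 * (t_edges[:-1] + t_edges[1:])
    p_cent = 0.5 * (p_edges[:-1] + p_edges[1:])
    solid = np.outer(np.cos(t_edges[:-1]) - np.cos(t_edges[1:]), np.diff(p_edges))
    n = len(local)
    angular = ang_counts / max(n, 1) / solid          # probability per steradian
    # spherical-harmonic expansion of the angular density from the samples
    tt, pp = np.meshgrid(t_cent, p_cent, indexing="ij")
    recon = np.zeros_like(angular)
    if n > 0:
        for l in range(l_max + 1):
            for m in range(-l, l + 1):
                flm = np.mean(np.conj(sph_harm_y(l, m, theta_s, phi_s)))
                recon = recon + np.real(flm * sph_harm_y(l, m, tt, pp))
    recon = np.clip(recon, 0.0, None)
    return SdfGrid(frame, r_min, r_max, hist, edges, angular, recon,
                   t_cent, p_cent, l_max, n, n_frames)


def iso_level_for_fraction(sdf_or_density, fraction: float) -> float:
    """Largest density level whose superlevel set encloses >= ``fraction``.

    Operates on the normalized 3D histogram (probability per voxel, returned
    as probability density per cubic angstrom).  Monotone non-increasing in
    the fraction.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if isinstance(sdf_or_density, SdfGrid):
        hist = sdf_or_density.hist
        voxel = np.diff(sdf_or_density.edges)[0] ** 3
    else:
        hist = np.asarray(sdf_or_density, dtype=float)
        hist = hist / hist.sum()
        voxel = 1.0
    flat = np.sort(hist.ravel())[::-1]
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, fraction - 1e-12))
    k = min(k, len(flat) - 1)
    return float(flat[k] / voxel)


def enclosed_fraction(sdf: SdfGrid, level: float) -> float:
    """Probability mass of the superlevel set {density >= level}."""
    voxel = np.diff(sdf.edges)[0] ** 3
    return float(sdf.hist[sdf.hist / voxel >= level].sum())


def enclosed_mass_at_fraction(sdf_or_density, fraction: float) -> float:
    """Mass of the minimal top-density voxel set reaching >= ``fraction``.

    This is the mass actually enclosed by an iso-surface drawn at
    :func:`iso_level_for_fraction`; ties at the threshold density are broken
    by taking only as many voxels as needed (relevant for uniform densities,
    where every level's strict superlevel set is all-or-nothing).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    hist = sdf_or_density.hist if isinstance(sdf_or_density, SdfGrid) else (
        np.asarray(sdf_or_density, dtype=float))
    hist = hist / hist.sum()
    flat = np.sort(hist.ravel())[::-1]
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, fraction - 1e-12))
    return float(cum[min(k, len(cum) - 1)])


def project_sdf(sdf: SdfGrid, plane: str, scale: str = "probability") -> np.ndarray:
    """Line-integral projection of the 3D histogram onto a coordinate plane.

    Total mass is conserved.  ``scale='probability'`` projects the normalized
    histogram (each map integrates to 1); ``scale='per_frame'`` projects the
    average neighbor count per molecule-frame, putting paired maps from
    different origins on one shared intensity scale.
    """
    axis = {"yz": 0, "xz": 1, "xy": 2}.get(plane)
    if axis is None:
        raise ValueError(f"unknown plane {plane!r}")
    if scale == "probability":
        grid = sdf.hist
    elif scale == "per_frame":
        grid = sdf.per_frame_hist
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return grid.sum(axis=axis)
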