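import numpy as np
import pytest

from solvshell.analysis import (
    LocalFrame,
    average_rdfs,
    classify_rotamer,
    collect_torsions,
    compute_rdf,
    compute_sdf,
    coordination_number,
    direct_coordination,
    enclosed_mass_at_fraction,
    find_first_maximum,
    find_first_minimum,
    iso_level_for_fraction,
    project_sdf,
    rotamer_populations_from_samples,
    torsion_statistics,
)
from solvshell.ensemble import (
    Configuration,
    Ensemble,
    SimulationBox,
    build_molecule,
    cellobiose_template,
)
from solvshell.generator import GeneratorParams, generate_ensemble
from solvshell.geometry import minimum_image_displacement
from solvshell.scattering import Rdf


def bare_atom_config(positions, box, site_class="Ow"):
    """Monatomic configuration (each atom its own molecule)."""
    n = len(positions)
    return Configuration(
        box=box, positions=np.asarray(positions, float),
        elements=np.array(["O"] * n, dtype="U2"),
        site_class=np.array([site_class] * n, dtype="U2"),
        role=np.array([""] * n, dtype="U4"),
        exchangeable=np.zeros(n, dtype=bool),
        molecule_id=np.arange(n),
        residue=np.array(["water"] * n, dtype="U12"))


class TestComputeRdf:
    def test_ideal_gas_normalization(self):
        rng = np.random.default_rng(0)
        box = SimulationBox((20.0, 20.0, 20.0))
        configs = [bare_atom_config(rng.uniform(0, 20, (300, 3)), box)
                   for _ in range(60)]
        rdf = compute_rdf(Ensemble(configs), ("Ow", "Ow"), dr=0.25, r_max=9.0)
        mask = rdf.r > 1.0
        assert np.all(np.abs(rdf.g[mask] - 1.0) < 0.05)

    def test_two_fixed_atoms_occupy_single_bin(self):
        box = SimulationBox((20.0, 20.0, 20.0))
        d = 3.17
        cfg = bare_atom_config([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]], box)
        rdf = compute_rdf(Ensemble([cfg]), ("Ow", "Ow"), dr=0.1, r_max=9.0)
        occupied = np.flatnonzero(rdf.g > 0)
        assert len(occupied) == 1
        assert abs(rdf.r[occupied[0]] - d) <= 0.05

    def test_histogram_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(3)
        box = SimulationBox((12.0, 12.0, 12.0))
        pos = rng.uniform(0, 12, (100, 3))
        cfg = bare_atom_config(pos, box)
        dr, r_max = 0.2, 5.8
        rdf = compute_rdf(Ensemble([cfg]), ("Ow", "Ow"), dr=dr, r_max=r_max)
        edges = np.arange(0.0, r_max + 0.5 * dr, dr)
        brute = np.zeros(len(edges) - 1)
        for i in range(100):
            for j in range(100):
                if i == j:
                    continue
                d = np.linalg.norm(minimum_image_displacement(
                    pos[i], pos[j], (12.0, 12.0, 12.0)))
                k = np.searchsorted(edges, d, side="left") - 1
                if 0 <= k < len(brute):
                    brute[k] += 1
        shell = 4 * np.pi / 3 * (edges[1:] ** 3 - edges[:-1] ** 3)
        rho = 100 / 12.0**3
        expected = brute / (100 * shell * rho * 1.0)
        np.testing.assert_allclose(rdf.g, expected, atol=1e-12)

    def test_empty_selection_raises(self, tiny_ensemble):
        with pytest.raises(ValueError, match="empty|role"):
            compute_rdf(tiny_ensemble, ("Zz", "Ow"), dr=0.1, r_max=5.0)

    def test_r_max_beyond_half_box_rejected(self, tiny_ensemble):
        L = min(tiny_ensemble.box.edge_lengths)
        with pytest.raises(ValueError):
            compute_rdf(tiny_ensemble, ("Ow", "Ow"), dr=0.1, r_max=0.6 * L)


class TestCoordination:
    def test_ideal_gas_closed_form(self):
        r = np.arange(0.05, 8.0, 0.02)
        rho, c_beta = 0.07, 0.4
        rdf = Rdf(("a", "b"), r, np.ones_like(r), rho, c_beta)
        n = coordination_number(rdf, 1.0, 3.0)
        expected = 4 * np.pi / 3 * rho * c_beta * (3.0**3 - 1.0**3)
        assert n.n_bar == pytest.approx(expected, rel=1e-3)

    def test_quadrature_agrees_with_direct_count(self, tiny_ensemble):
        pair = ("Ow", "Ow")
        dr = 0.05
        rdf = compute_rdf(tiny_ensemble, pair, dr=dr, r_max=6.0)
        quad = coordination_number(rdf, 2.0, 4.0)
        direct = direct_coordination(tiny_ensemble, pair, 2.0, 4.0)
        # agreement within one bin's worth of pairs at the shell edges
        r_edges_g = np.interp([2.0, 4.0], rdf.r, rdf.g)
        bin_pairs = 4 * np.pi * rdf.rho * rdf.c_beta * dr * (
            2.0**2 * r_edges_g[0] + 4.0**2 * r_edges_g[1])
        assert abs(quad.n_bar - direct.n_bar) <= bin_pairs + 1e-9

    def test_invalid_range_rejected(self):
        r = np.arange(0.05, 8.0, 0.02)
        rdf = Rdf(("a", "b"), r, np.ones_like(r), 0.05, 1.0)
        with pytest.raises(ValueError):
            coordination_number(rdf, 3.0, 1.0)

    def test_occupancy_recovery(self):
        p = 0.46  # the hydrogen-bond shell occupancy regime of interest
        params = GeneratorParams(n_solute=20, water_ratio=5,
                                 n_configurations=60, hbond_occupancy=p, seed=21)
        ens = generate_ensemble(params)
        rdf = compute_rdf(ens, ("O5p", "HO3"), dr=0.05, r_max=4.0, mode="intra")
        n = coordination_number(rdf, 1.5, 3.1)
        assert n.n_bar == pytest.approx(p, abs=0.03)


class TestFirstExtrema:
    def make_rdf(self, g_of_r, r_max=6.0, dr=0.02):
        r = np.arange(0.01, r_max, dr)
        return Rdf(("x", "y"), r, np.clip(g_of_r(r), 0, None), 0.1, 0.5)

    def test_constructed_max_and_min(self):
        rdf = self.make_rdf(lambda r: 1 + 1.5 * np.exp(-((r - 1.8) ** 2) / 0.08)
                            - 0.4 * np.exp(-((r - 2.46) ** 2) / 0.05))
        assert find_first_maximum(rdf) == pytest.approx(1.8, abs=0.03)
        assert find_first_minimum(rdf) == pytest.approx(2.46, abs=0.03)

    def test_monotone_curve_not_found(self):
        rdf = self.make_rdf(lambda r: 1 - np.exp(-r))
        assert find_first_minimum(rdf) is None
        assert find_first_maximum(rdf) is None

    def test_agreement_with_dense_grid_scan_on_random_curves(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            r0 = rng.uniform(1.5, 2.5)
            r1 = r0 + rng.uniform(0.5, 1.2)
            a = rng.uniform(0.6, 2.0)
            b = rng.uniform(0.2, 0.8)
            w0, w1 = rng.uniform(0.05, 0.12, 2)

            def g(r, a=a, b=b, r0=r0, r1=r1, w0=w0, w1=w1):
                return 1 + a * np.exp(-((r - r0) ** 2) / w0) \
                    - b * np.exp(-((r - r1) ** 2) / w1)

            rdf = self.make_rdf(g, dr=0.02)
            found = find_first_minimum(rdf)
            # dense-grid brute force on the analytic curve
            dense = np.arange(r0, 6.0, 1e-4)
            gd = g(dense)
            idx = np.flatnonzero((gd[1:-1] < gd[:-2]) & (gd[1:-1] <= gd[2:]))
            expected = dense[idx[0] + 1]
            assert found == pytest.approx(expected, abs=0.05)


class TestTorsionStatistics:
    def test_delta_distribution(self):
        samples = np.full(500, 22.0)
        dist = torsion_statistics(samples, "phi_H", window=(-20, 70))
        assert dist.peak_mean == pytest.approx(22.0, abs=1.0)
        assert dist.gaussian_mean == pytest.approx(22.0, abs=1.0)

    def test_gaussian_recovery(self):
        rng = np.random.default_rng(12)
        samples = rng.normal(-40.0, 10.0, 4000)
        dist = torsion_statistics(samples, "psi_H", window=(-90, 10))
        assert dist.gaussian_mean == pytest.approx(-40.0, abs=2.0)
        assert dist.gaussian_sigma == pytest.approx(10.0, abs=2.0)

    def test_secondary_mode_outside_window_does_not_shift_means(self):
        rng = np.random.default_rng(13)
        main = rng.normal(22.0, 8.0, 3520)
        minor = rng.normal(150.0, 8.0, 480)  # 12% secondary conformation
        with_minor = torsion_statistics(np.concatenate([main, minor]),
                                        "phi_H", window=(-20, 70))
        without = torsion_statistics(main, "phi_H", window=(-20, 70))
        assert abs(with_minor.gaussian_mean - without.gaussian_mean) < 1.0
        assert abs(with_minor.peak_mean - without.peak_mean) < 1.0

    def test_window_straddling_180_is_circular(self):
        rng = np.random.default_rng(14)
        samples = np.array([((180.0 + x + 180) % 360) - 180
                            for x in rng.normal(0, 8.0, 2000)])
        dist = torsion_statistics(samples, "omega", window=(150.0, 210.0))
        assert abs(abs(dist.gaussian_mean) - 180.0) < 2.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            torsion_statistics(np.zeros(10), "x", window=(50.0, 50.0))

    def test_collect_torsions_matches_generator_means(self, tiny_ensemble):
        phis = collect_torsions(tiny_ensemble, "phi_H")
        assert len(phis) == 3 * 4  # solutes x configurations
        assert abs(np.mean(phis) - 22.0) < 15.0


class TestRotamers:
    @pytest.mark.parametrize("omega,expected", [
        (65.0, "gt"), (-65.0, "gg"), (180.0, "tg"), (0.0, "gt"),
        (100.0, "gt"), (-100.0, "gg"), (140.0, "tg"), (-140.0, "tg"),
    ])
    def test_classification(self, omega, expected):
        assert classify_rotamer(omega) == expected

    def test_population_recovery_exact_under_bounded_jitter(self):
        rng = np.random.default_rng(15)
        pops = (0.5, 0.3, 0.2)
        refs = [65.0, -65.0, 180.0]
        draws = rng.choice(3, p=pops, size=3000)
        jitter = rng.uniform(-50.0, 50.0, 3000)  # jitter < 55 deg
        omegas = np.array([refs[k] for k in draws]) + jitter
        got = rotamer_populations_from_samples(omegas)
        counts = np.bincount(draws, minlength=3) / 3000
        assert got.as_tuple() == pytest.approx(tuple(counts), abs=1e-12)


class TestAnomerAveraging:
    def test_weighted_average_equals_pooled_rdf(self):
        params = GeneratorParams(n_solute=10, water_ratio=8,
                                 n_configurations=6, seed=33)
        ens = generate_ensemble(params)
        dr, r_max = 0.1, 5.0
        g_a = compute_rdf(ens, ("O4a", "Hw"), dr=dr, r_max=r_max)
        g_b = compute_rdf(ens, ("O4b", "Hw"), dr=dr, r_max=r_max)
        pooled = compute_rdf(ens, (("O4a", "O4b"), "Hw"), dr=dr, r_max=r_max)
        n_a, n_b = g_a.meta["n_alpha"], g_b.meta["n_alpha"]
        avg = average_rdfs([g_a, g_b], [n_a, n_b])
        np.testing.assert_allclose(avg.g, pooled.g, atol=1e-10)


def synthetic_sdf_ensemble(directions, radius=2.5):
    """One solute plus probe 'water' oxygens at given local-frame directions."""
    template = cellobiose_template()
    frag = build_molecule(template, "beta")
    frag.positions += 15.0
    frame = LocalFrame()
    i_o = frag.index_of("O5p")
    axes = frame.axes(frag.positions[i_o],
                      frag.positions[frag.index_of("C1p")],
                      frag.positions[frag.index_of("C5p")],
                      frag.positions[frag.index_of("C6p")])
    origin = frag.positions[i_o]
    probes = origin + radius * np.asarray(directions) @ axes
    box = SimulationBox((40.0, 40.0, 40.0))
    n = len(probes)
    probe_cfg = Configuration(
        box=box,
        positions=np.vstack([frag.positions, probes]),
        elements=np.concatenate([frag.elements, np.array(["O"] * n, dtype="U2")]),
        site_class=np.concatenate([frag.site_class, np.array(["Ow"] * n, dtype="U2")]),
        role=np.concatenate([frag.role, np.array([""] * n, dtype="U4")]),
        exchangeable=np.concatenate([frag.exchangeable, np.zeros(n, dtype=bool)]),
        molecule_id=np.concatenate([np.zeros(frag.n_atoms, dtype=int),
                                    np.arange(1, n + 1)]),
        residue=np.concatenate([frag.residue, np.array(["water"] * n, dtype="U12")]),
    )
    return Ensemble([probe_cfg]), frame


class TestSdf:
    def test_isotropic_targets_give_uniform_angular_density(self):
        rng = np.random.default_rng(19)
        dirs = rng.normal(size=(4000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ens, frame = synthetic_sdf_ensemble(dirs)
        sdf = compute_sdf(ens, frame, "Ow", r_max=3.0, n_theta=6, n_phi=12)
        # Poisson check on raw per-bin counts: every bin within 4 sigma and
        # the reduced chi-square near 1 (72 bins, so a single 3-sigma
        # excursion is expected by chance)
        solid = 4 * np.pi / (6 * 12)
        raw = sdf.angular * sdf.n_samples * solid
        expected = sdf.n_samples / (6 * 12)
        assert np.all(np.abs(raw - expected) < 4 * np.sqrt(expected))
        chi2_red = np.mean((raw - expected) ** 2 / expected)
        assert chi2_red < 1.6

    def test_targets_along_z_concentrate_in_upper_hemisphere(self):
        rng = np.random.default_rng(20)
        dirs = np.column_stack([rng.normal(0, 0.3, 500),
                                rng.normal(0, 0.3, 500),
                                np.ones(500)])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ens, frame = synthetic_sdf_ensemble(dirs)
        sdf = compute_sdf(ens, frame, "Ow", r_max=3.0)
        nz = sdf.hist.shape[2]
        upper = sdf.hist[:, :, nz // 2:].sum()
        assert upper >= 0.95
        # reconstructed (spherical-harmonic) mass also sits at +z; the mass
        # integral weights each row by its solid angle
        w = np.sin(sdf.theta)[:, None]
        mass = sdf.angular_sh * w
        assert mass[sdf.theta < np.pi / 2, :].sum() / mass.sum() >= 0.95

    def test_reconstruction_matches_histogram_on_generator_output(self):
        params = GeneratorParams(n_solute=5, water_ratio=63,
                                 n_configurations=20, seed=44)
        ens = generate_ensemble(params)
        sdf = compute_sdf(ens, LocalFrame(), "Ow", r_max=5.0, l_max=8,
                          n_theta=8, n_phi=16)
        a, b = sdf.angular.ravel(), sdf.angular_sh.ravel()
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos >= 0.9

    def test_degenerate_frame_rejected(self):
        frame = LocalFrame()
        with pytest.raises(ValueError, match="degenerate"):
            frame.axes(np.zeros(3), np.array([1.0, 0, 0]),
                       np.array([2.0, 0, 0]), np.array([0, 0, 1.0]))


class TestIsoLevels:
    def test_fraction_one_returns_minimum_density(self):
        rng = np.random.default_rng(23)
        d = rng.uniform(0.1, 1.0, (6, 6, 6))
        level = iso_level_for_fraction(d, 1.0)
        assert level == pytest.approx((d / d.sum()).min())

    def test_uniform_density_mass(self):
        u = np.ones((10, 10, 10))
        assert enclosed_mass_at_fraction(u, 0.8) == pytest.approx(0.80, abs=0.02)

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(24)
        d = rng.exponential(size=(8, 8, 8))
        levels = [iso_level_for_fraction(d, f) for f in (0.25, 0.5, 0.8)]
        assert levels[0] >= levels[1] >= levels[2]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            iso_level_for_fraction(np.ones((2, 2, 2)), 0.0)


class TestProjections:
    def test_mass_conservation(self, tiny_ensemble):
        sdf = compute_sdf(tiny_ensemble, LocalFrame(), "Ow", r_max=4.0)
        for plane in ("yz", "xz", "xy"):
            proj = project_sdf(sdf, plane)
            assert proj.sum() == pytest.approx(sdf.hist.sum(), abs=1e-10)

    def test_mirror_symmetric_density_projects_symmetrically(self):
        rng = np.random.default_rng(25)
        dirs = rng.normal(size=(2000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        dirs = np.vstack([dirs, dirs * np.array([1.0, -1.0, 1.0])])  # mirror in y
        ens, frame = synthetic_sdf_ensemble(dirs)
        sdf = compute_sdf(ens, frame, "Ow", r_max=3.0, n_grid=16)
        xz = project_sdf(sdf, "xz")  # (x, z) map, y integrated out: unchanged
        xy = project_sdf(sdf, "xy")  # (x, y) map should mirror in y
        np.testing.assert_allclose(xy, xy[:, ::-1], atol=2e-3)

    def test_two_to_one_density_scaling_on_shared_scale(self):
        rng = np.random.default_rng(26)
        half = np.column_stack([rng.normal(0, 0.2, 300),
                                rng.normal(0, 0.2, 300), np.ones(300)])
        half /= np.linalg.norm(half, axis=1, keepdims=True)
        dirs = np.repeat(half, 2, axis=0)  # exactly twice the density
        ens1, frame = synthetic_sdf_ensemble(dirs)
        ens2, _ = synthetic_sdf_ensemble(half)
        sdf1 = compute_sdf(ens1, frame, "Ow", r_max=3.0, n_grid=12)
        sdf2 = compute_sdf(ens2, frame, "Ow", r_max=3.0, n_grid=12)
        p1 = project_sdf(sdf1, "yz", scale="per_frame")
        p2 = project_sdf(sdf2, "yz", scale="per_frame")
        assert p1.max() / p2.max() == pytest.approx(2.0, rel=0.05)

    def test_unknown_plane(self, tiny_ensemble):
        sdf = compute_sdf(tiny_ensemble, LocalFrame(), "Ow", r_max=3.0)
        with pytest.raises(ValueError):
            project_sdf(sdf, "zz")
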