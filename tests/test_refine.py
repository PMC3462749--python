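import numpy as np
import pytest

from solvshell.ensemble import (
    Configuration,
    Ensemble,
    SimulationBox,
    build_molecule,
    cellobiose_template,
    water_template,
)
from solvshell.generator import GeneratorParams, generate_ensemble, synthesize_target_fq
from solvshell.geometry import rotation_about_axis
from solvshell.refine import (
    KB,
    EmpiricalPotential,
    LJSite,
    MoveSet,
    PairPotential,
    System,
    build_system,
    default_potential,
    mc_step,
    metropolis_accept,
    refine,
    system_energy,
    update_empirical_potential,
)
from solvshell.scattering import TotalStructureFactor

import toys


def two_site_config(d, site_class="Ow", box_edge=50.0):
    box = SimulationBox((box_edge,) * 3)
    pos = np.array([[10.0, 10.0, 10.0], [10.0 + d, 10.0, 10.0]])
    return Configuration(
        box=box, positions=pos,
        elements=np.array(["O", "O"], dtype="U2"),
        site_class=np.array([site_class] * 2, dtype="U2"),
        role=np.array(["", ""], dtype="U4"),
        exchangeable=np.zeros(2, dtype=bool),
        molecule_id=np.arange(2),
        residue=np.array(["water"] * 2, dtype="U12"))


NEUTRAL_LJ = PairPotential({"Ow": LJSite(0.8, 3.0, 0.0)})


class TestEnergy:
    def test_lj_zero_crossing_at_sigma(self):
        e = system_energy(two_site_config(3.0), NEUTRAL_LJ, cutoff=20.0)
        # truncation shift at the cutoff is the only residual term
        assert e == pytest.approx(0.0, abs=1e-3)

    def test_lj_minimum_depth(self):
        e = system_energy(two_site_config(2 ** (1 / 6) * 3.0), NEUTRAL_LJ, cutoff=20.0)
        assert e == pytest.approx(-0.8, abs=1e-3)

    def test_spce_dimer_scan(self, water_tmpl):
        """Hydrogen-bonded water dimer: minimum near 2.7-2.8 A O-O with a
        depth in the tens of kJ/mol (brute-force 1D scan)."""
        pot = default_potential()
        box = SimulationBox((50.0,) * 3)
        curve = {}
        for d in np.arange(2.4, 3.61, 0.05):
            for tilt in range(0, 181, 15):
                w1 = build_molecule(water_tmpl)
                v = w1.positions[1] - w1.positions[0]
                v /= np.linalg.norm(v)
                axis = np.cross(v, [1.0, 0, 0])
                ang = np.degrees(np.arccos(np.clip(v @ np.array([1.0, 0, 0]), -1, 1)))
                R1 = (rotation_about_axis(axis, ang)
                      if np.linalg.norm(axis) > 1e-9 else np.eye(3))
                w1.positions = (w1.positions - w1.positions[0]) @ R1.T
                w2 = build_molecule(water_tmpl)
                R2 = rotation_about_axis([0, 1, 0], tilt)
                w2.positions = (w2.positions - w2.positions[0]) @ R2.T
                w2.positions[:, 0] += d
                cfg = Configuration.from_fragments(box, [w1, w2])
                cfg.positions += 15
                e = system_energy(cfg, pot)
                key = round(d, 2)
                curve[key] = min(curve.get(key, np.inf), e)
        r_min = min(curve, key=curve.get)
        assert 2.7 <= r_min <= 2.8
        assert -30.0 <= curve[r_min] <= -18.0

    def test_translation_invariance(self, tiny_ensemble):
        cfg = tiny_ensemble.configurations[0]
        pot = default_potential()
        e0 = system_energy(cfg, pot)
        shifted = Configuration(**{**cfg.__dict__,
                                   "positions": cfg.positions + np.array([3.1, -8.7, 0.4])})
        assert system_energy(shifted, pot) == pytest.approx(e0, rel=1e-9)

    def test_quarter_turn_rotation_invariance(self, tiny_ensemble):
        cfg = tiny_ensemble.configurations[0]
        pot = default_potential()
        e0 = system_energy(cfg, pot)
        L = cfg.box.edge_lengths[0]
        rotated = cfg.positions[:, [1, 0, 2]] * np.array([1.0, -1.0, 1.0])
        rotated[:, 1] += L  # bring back into the box frame
        r_cfg = Configuration(**{**cfg.__dict__, "positions": rotated})
        assert system_energy(r_cfg, pot) == pytest.approx(e0, rel=1e-9)

    def test_clash_is_clamped_and_flagged(self):
        cfg = two_site_config(0.05)
        system = System(cfg, NEUTRAL_LJ)
        e = system.total_energy()
        assert e >= 1e5
        assert system.clash_flagged

    def test_restraint_flat_bottom(self, template):
        frag = build_molecule(template, "beta")
        box = SimulationBox((30.0,) * 3)
        cfg = Configuration.from_fragments(box, [frag])
        cfg.positions += 10.0
        system = build_system(cfg, {0: (frag.torsions, frag.restraints, frag.bonds)})
        i, j = frag.index_of("H1p"), frag.index_of("H4")
        d = np.linalg.norm(cfg.positions[i] - cfg.positions[j])
        assert abs(d - 2.205) < 0.3  # built geometry satisfies the restraint
        assert system.restraint_energy() == 0.0


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-1e-9, 300.0, rng) for _ in range(100))
        assert all(metropolis_accept(-50.0, 300.0, rng) for _ in range(100))

    def test_infinite_temperature_accepts_everything(self):
        system = System(toys.water_box_config(16, 0.08, 3), default_potential())
        rng = np.random.default_rng(1)
        acc = sum(mc_step(system, MoveSet(), 1e12, rng) for _ in range(1000))
        # hard-core overlaps still reject at any finite temperature; the
        # acceptance fraction approaches one from below
        assert acc / 1000 > 0.995

    def test_two_state_boltzmann_ratio(self):
        """A two-level toy sampled through the acceptance rule visits states
        in the analytic Boltzmann ratio."""
        dE = 3.0  # kJ/mol
        T = 298.0
        rng = np.random.default_rng(8)
        state = 0
        visits = np.zeros(2)
        for _ in range(100_000):
            proposed = 1 - state
            dU = dE if proposed == 1 else -dE
            if metropolis_accept(dU, T, rng):
                state = proposed
            visits[state] += 1
        expected = np.exp(-dE / (KB * T))
        ratio = visits[1] / visits[0]
        p = expected / (1 + expected)
        sigma = np.sqrt(p * (1 - p) / 100_000)
        assert abs(visits[1] / visits.sum() - p) < 3 * sigma * (1 + 1 / p)
        assert ratio == pytest.approx(expected, rel=0.1)

    def test_zero_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)

    def test_torsion_moves_preserve_bonded_geometry(self, template):
        frag = build_molecule(template, "beta")
        box = SimulationBox((30.0,) * 3)
        cfg = Configuration.from_fragments(box, [frag])
        cfg.positions += 12.0
        system = build_system(cfg, {0: (frag.torsions, frag.restraints, frag.bonds)})
        rng = np.random.default_rng(6)
        ms = MoveSet(weights=(0.0, 0.0, 1.0))  # torsion pivots only
        before = {(i, j): np.linalg.norm(cfg.positions[i] - cfg.positions[j])
                  for i, j in cfg.bonds}
        for _ in range(50):
            mc_step(system, ms, 500.0, rng)
        for (i, j), d in before.items():
            got = np.linalg.norm(system.config.positions[i]
                                 - system.config.positions[j])
            assert got == pytest.approx(d, abs=1e-9)


class TestEmpiricalPotentialUpdate:
    Q = np.arange(0.3, 15.0, 0.05)

    def _dataset(self, F, comp, b_map, scheme="s"):
        return TotalStructureFactor(scheme, self.Q, F, comp, b_map)

    def test_zero_residual_is_fixed_point(self):
        comp = {"Ow": 1 / 3, "Hw": 2 / 3}
        b = {"Ow": 5.8, "Hw": -3.7}
        F = np.sin(self.Q) / self.Q
        targets = [self._dataset(F, comp, b)]
        models = [self._dataset(F.copy(), comp, b)]
        ep = EmpiricalPotential.zeros(np.arange(0.1, 8, 0.1))
        new, _ = update_empirical_potential(targets, models, ep, rho=0.1)
        for U in new.tables.values():
            np.testing.assert_allclose(U, 0.0, atol=1e-14)

    def test_linearity_of_increment(self):
        comp = {"Ow": 1 / 3, "Hw": 2 / 3}
        b = {"Ow": 5.8, "Hw": -3.7}
        zero = np.zeros_like(self.Q)
        resid = np.exp(-((self.Q - 3) ** 2)) * 2.0
        ep = EmpiricalPotential.zeros(np.arange(0.1, 8, 0.1), amplitude_cap=1e6)
        one, _ = update_empirical_potential(
            [self._dataset(zero, comp, b)], [self._dataset(resid, comp, b)], ep, rho=0.1)
        two, _ = update_empirical_potential(
            [self._dataset(zero, comp, b)], [self._dataset(2 * resid, comp, b)], ep, rho=0.1)
        for pair in one.tables:
            np.testing.assert_allclose(two.tables[pair], 2 * one.tables[pair],
                                       rtol=1e-9, atol=1e-12)

    def test_increment_never_exceeds_cap(self):
        comp = {"Ow": 1 / 3, "Hw": 2 / 3}
        b = {"Ow": 5.8, "Hw": -3.7}
        zero = np.zeros_like(self.Q)
        huge = np.full_like(self.Q, 50.0)
        ep = EmpiricalPotential.zeros(np.arange(0.1, 8, 0.1), amplitude_cap=2.0)
        new, _ = update_empirical_potential(
            [self._dataset(zero, comp, b)], [self._dataset(huge, comp, b)], ep, rho=0.1)
        for U in new.tables.values():
            assert np.max(np.abs(U)) <= 2.0 + 1e-12

    def test_invisible_pair_skipped(self):
        comp = {"Ow": 0.5, "Hw": 0.5}
        b = {"Ow": 5.8, "Hw": 0.0}  # Hw invisible in this dataset
        zero = np.zeros_like(self.Q)
        resid = np.sin(self.Q)
        ep = EmpiricalPotential.zeros(np.arange(0.1, 8, 0.1))
        new, skipped = update_empirical_potential(
            [self._dataset(zero, comp, b)], [self._dataset(resid, comp, b)], ep, rho=0.1)
        assert ("Hw", "Hw") in skipped
        assert ("Ow", "Hw") in skipped or ("Hw", "Ow") in skipped


class TestRefineLoop:
    def test_self_targets_are_a_fixed_point(self, tiny_ensemble):
        """Refining against targets synthesized from the starting ensemble
        itself leaves chi-squared at zero and the potential untouched."""
        sub = Ensemble(tiny_ensemble.configurations[:2])
        targets = synthesize_target_fq(sub, noise_sd=0.0, dr=0.1,
                                       Q=np.arange(0.3, 15.0, 0.05))
        system = build_system(sub.configurations[0])
        ens, history = refine(system, targets, n_outer=2, steps=0,
                              initial_ensemble=sub, rdf_dr=0.1, seed=4)
        for state in history:
            assert max(state.chi2_per_dataset) <= 1e-10
        for U in system.ep.tables.values():
            np.testing.assert_allclose(U, 0.0, atol=1e-12)

    def test_restraints_hold_during_refinement(self):
        params = GeneratorParams(n_solute=2, water_ratio=20,
                                 n_configurations=1, seed=77)
        ens = generate_ensemble(params)
        cfg = ens.configurations[0]
        template = cellobiose_template()
        frag = build_molecule(template)
        topo = {m: (frag.torsions, frag.restraints, frag.bonds) for m in range(2)}
        system = build_system(cfg, topo)
        targets = synthesize_target_fq(ens, noise_sd=0.0, dr=0.1,
                                       Q=np.arange(0.3, 15.0, 0.05))
        refined, history = refine(system, targets[:2], n_outer=2, steps=400,
                                  sample_every=40, rdf_dr=0.1, seed=5)
        i = {r: k for k, r in enumerate(cfg.role[cfg.molecule_id == 0])}
        ok = total = 0
        for snap in refined:
            for mid in (0, 1):
                idx = np.flatnonzero(snap.molecule_id == mid)
                rmap = {r: j for j, r in zip(idx, snap.role[idx])}
                d = np.linalg.norm(snap.positions[rmap["H1p"]]
                                   - snap.positions[rmap["H4"]])
                total += 1
                ok += abs(d - 2.205) <= 0.3
        assert ok / total >= 0.99
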