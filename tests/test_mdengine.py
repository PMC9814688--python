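"""Energies, forces, the R_g restraint, Langevin sampling and the
MC-volume barostat."""

import numpy as np
import pytest

from cononsol.forcefield import (LambdaScaling, PairMode, R_GAS, Species,
                                 build_forcefield,
                                 default_polymer_species, lj_energy_force)
from cononsol.mdengine import (IntegratorSpec, MCBarostat,
                               PositionRestraint, RgRestraint, SystemState,
                               Topology, check_molecule_integrity,
                               compute_rg, draw_maxwell_velocities,
                               kinetic_energy, langevin_step, minimize,
                               rg_restraint_energy_forces, run_segment,
                               total_energy_forces, virial_pressure)
from cononsol.synth import ReducedSolventSpec, build_mixture, \
    make_polymer_chain


def _fd_forces(state, ff, restraints=(), h=1e-6):
    """Central finite differences of the total potential."""
    fd = np.zeros_like(state.positions)
    for i in range(len(state.positions)):
        for k in range(3):
            state.positions[i, k] += h
            ep, _ = total_energy_forces(state, ff, restraints)
            state.positions[i, k] -= 2 * h
            em, _ = total_energy_forces(state, ff, restraints)
            state.positions[i, k] += h
            fd[i, k] = -(ep["potential"] - em["potential"]) / (2 * h)
    return fd


class TestRadiusOfGyration:
    def test_coincident_points(self):
        pos = np.zeros((5, 3))
        pos += [1.0, 2.0, 3.0]
        assert compute_rg(pos, np.arange(5)) == 0.0

    def test_two_points(self):
        pos = np.array([[0.0, 0, 0], [0.8, 0, 0]])
        assert compute_rg(pos, np.arange(2)) == pytest.approx(0.4)

    def test_matches_pairwise_double_loop(self):
        # independent identity: Rg^2 = (1/2N^2) sum_ij |ri - rj|^2
        rng = np.random.default_rng(3)
        pos = rng.standard_normal((32, 3))
        n = 32
        acc = 0.0
        for i in range(n):
            for j in range(n):
                acc += ((pos[i] - pos[j]) ** 2).sum()
        rg_ref = np.sqrt(acc / (2 * n * n))
        assert compute_rg(pos, np.arange(n)) == pytest.approx(rg_ref,
                                                              rel=1e-12)

    def test_single_particle_rejected(self):
        with pytest.raises(ValueError):
            compute_rg(np.zeros((3, 3)), np.array([0]))


class TestRgRestraint:
    sel = np.arange(8)

    def test_zero_at_target(self, chain8):
        rg = compute_rg(chain8.positions, self.sel)
        r = RgRestraint(k_b=20000.0, rg0=rg, selection=self.sel)
        e, f = rg_restraint_energy_forces(chain8.positions, r)
        assert e == pytest.approx(0.0, abs=1e-16)
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_forces_match_finite_difference(self, chain8):
        r = RgRestraint(k_b=20000.0, rg0=0.7, selection=self.sel)
        _, f = rg_restraint_energy_forces(chain8.positions, r)
        h = 1e-7
        for i in (0, 3, 7):
            for k in range(3):
                chain8.positions[i, k] += h
                ep, _ = rg_restraint_energy_forces(chain8.positions, r)
                chain8.positions[i, k] -= 2 * h
                em, _ = rg_restraint_energy_forces(chain8.positions, r)
                chain8.positions[i, k] += h
                assert f[i, k] == pytest.approx(-(ep - em) / (2 * h),
                                                rel=1e-6, abs=1e-4)

    def test_translation_invariance_and_zero_net_force(self, chain8):
        r = RgRestraint(k_b=5000.0, rg0=0.5, selection=self.sel)
        e1, f1 = rg_restraint_energy_forces(chain8.positions, r)
        e2, f2 = rg_restraint_energy_forces(chain8.positions + 3.3, r)
        assert e2 == pytest.approx(e1, rel=1e-12)
        assert np.allclose(f1, f2, atol=1e-10)
        assert np.allclose(f1.sum(axis=0), 0.0, atol=1e-9)

    def test_degenerate_gradient_raises(self):
        r = RgRestraint(k_b=1.0, rg0=0.5, selection=np.arange(4))
        with pytest.raises(ValueError):
            rg_restraint_energy_forces(np.zeros((4, 3)), r)


class TestEnergiesAndForces:
    def test_isolated_pair_reduces_to_lj(self):
        ff = build_forcefield([default_polymer_species()],
                              scaling=LambdaScaling(1.0, 1.0))
        pos = np.array([[2.0, 2.0, 2.0], [2.5, 2.0, 2.0]])
        st = SystemState(pos, np.zeros_like(pos), np.full(3, 6.0),
                         np.zeros(2, dtype=np.int64), Topology.empty(2))
        terms, forces = total_energy_forces(st, ff)
        u_ref, f_ref = lj_energy_force(0.5, ff.pair(0, 0))
        assert terms["potential"] == pytest.approx(u_ref, rel=1e-12)
        assert forces[0, 0] == pytest.approx(-f_ref, rel=1e-12)

    def test_kernel_matches_python_brute_force(self):
        # 50-particle mixed LJ/WCA fixture vs a plain double loop
        spec = ReducedSolventSpec()
        st, ff, _ = build_mixture(spec, 0.3, 50, 2.2, seed=5)
        terms, _ = total_energy_forces(st, ff)
        pos, box, sp = st.positions, st.box, st.species_index
        e_ref = 0.0
        two6 = 2 ** (1 / 6)
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = pos[i] - pos[j]
                d -= box * np.rint(d / box)
                r = np.sqrt((d * d).sum())
                s, e = ff.sigma[sp[i], sp[j]], ff.epsilon[sp[i], sp[j]]
                mode = ff.mode[sp[i], sp[j]]
                if mode == int(PairMode.LJ) and r < ff.cutoff:
                    e_ref += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
                elif mode == int(PairMode.WCA) and r < two6 * s:
                    e_ref += 4 * e * ((s / r) ** 12 - (s / r) ** 6) + e
        pair_total = terms["lj"] + terms["wca"]
        assert pair_total == pytest.approx(e_ref, rel=1e-10)

    def test_forces_match_finite_difference_all_terms(self, chain8,
                                                      polymer_ff):
        restraints = [
            RgRestraint(k_b=500.0, rg0=0.6, selection=np.arange(8)),
            PositionRestraint(k_pr=300.0,
                              reference_positions=chain8.positions[:3] + 0.1,
                              selection=np.arange(3)),
        ]
        _, forces = total_energy_forces(chain8, polymer_ff, restraints)
        fd = _fd_forces(chain8, polymer_ff, restraints)
        assert np.allclose(forces, fd, rtol=1e-5, atol=1e-3)

    def test_newton_third_law(self, chain8, polymer_ff):
        _, forces = total_energy_forces(chain8, polymer_ff)
        assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-8)

    def test_overlap_guard(self, polymer_ff):
        pos = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0 + 1e-6]])
        st = SystemState(pos, np.zeros_like(pos), np.full(3, 6.0),
                         np.zeros(2, dtype=np.int64), Topology.empty(2))
        with pytest.raises(RuntimeError, match="overlap"):
            total_energy_forces(st, polymer_ff)

    def test_minimum_image_requires_large_enough_box(self, polymer_ff):
        pos = np.array([[0.5, 0.5, 0.5], [1.0, 1.0, 1.0]])
        st = SystemState(pos, np.zeros_like(pos), np.full(3, 2.0),
                         np.zeros(2, dtype=np.int64), Topology.empty(2))
        with pytest.raises(ValueError, match="box"):
            total_energy_forces(st, polymer_ff)  # 2.0 < 2 * 1.4

    def test_broken_molecule_guard(self):
        pos = np.array([[0.1, 0.5, 0.5], [3.5, 0.5, 0.5]])
        topo = Topology(np.array([[0, 1]]), np.zeros((0, 3), np.int64),
                        np.zeros(2, np.int64))
        st = SystemState(pos, np.zeros_like(pos), np.full(3, 6.0),
                         np.zeros(2, dtype=np.int64), topo)
        with pytest.raises(RuntimeError, match="broken"):
            check_molecule_integrity(st)


class TestLangevin:
    def test_symplectic_limit_energy_conservation(self, polymer_ff):
        # friction -> infinity (no noise at T -> 0): velocity Verlet on
        # an LJ dimer conserves energy to < 1e-5 kJ/mol per step
        pos = np.array([[3.0, 3.0, 3.0], [3.46, 3.0, 3.0]])
        vel = np.zeros_like(pos)
        st = SystemState(pos, vel, np.full(3, 6.0),
                         np.zeros(2, dtype=np.int64), Topology.empty(2),
                         rng=np.random.default_rng(0))
        spec = IntegratorSpec(dt=0.002, temperature=0.0,
                              friction_time=1e12)
        m = polymer_ff.masses[st.species_index]
        energies = []
        forces = None
        for _ in range(400):
            forces, terms = langevin_step(st, polymer_ff, [], spec, forces)
            energies.append(terms["potential"]
                            + kinetic_energy(st, polymer_ff.masses))
        drift = abs(energies[-1] - energies[0]) / len(energies)
        assert drift < 1e-5

    def test_determinism_same_seed(self, polymer_ff):
        def run(seed):
            st = make_polymer_chain(8)
            st.rng = np.random.default_rng(seed)
            draw_maxwell_velocities(st, polymer_ff, 300.0)
            run_segment(st, polymer_ff, [], IntegratorSpec(), 50)
            return st.positions.copy()

        assert np.array_equal(run(42), run(42))
        assert not np.array_equal(run(42), run(43))

    def test_equipartition_lj_fluid(self):
        spec = ReducedSolventSpec()
        st, ff, _ = build_mixture(spec, 0.0, 80, 2.2, seed=9)
        st.rng = np.random.default_rng(10)
        draw_maxwell_velocities(st, ff, 300.0)
        minimize(st, ff, max_steps=100, tol=500.0)
        ispec = IntegratorSpec()
        run_segment(st, ff, [], ispec, 2000)
        rec = run_segment(st, ff, [], ispec, 12000, observer_stride=20,
                          observers=[lambda s, t: {
                              "ke": kinetic_energy(s, ff.masses)}])
        ke = rec.column("ke").mean()
        per_dof = ke / (3 * st.n_particles)
        assert per_dof == pytest.approx(0.5 * R_GAS * 300.0, rel=0.02)

    def test_harmonic_well_gaussian_distribution(self):
        # single light particle tethered in a stiff well: positions are
        # exactly Gaussian with variance RT/k per dimension (KS check)
        from scipy.stats import kstest

        k = 1000.0
        light = Species("L", 0.3, 0.1, 1.0, "water")
        ff = build_forcefield([light])
        pos = np.array([[3.0, 3.0, 3.0]])
        st = SystemState(pos, np.zeros_like(pos), np.full(3, 6.0),
                         np.zeros(1, dtype=np.int64), Topology.empty(1),
                         rng=np.random.default_rng(123))
        restr = PositionRestraint(k_pr=k, reference_positions=pos.copy(),
                                  selection=np.array([0]))
        ispec = IntegratorSpec()
        draw_maxwell_velocities(st, ff, 300.0)
        run_segment(st, ff, [restr], ispec, 500)
        rec = run_segment(st, ff, [restr], ispec, 25 * 4000,
                          observer_stride=25,
                          observers=[lambda s, t: {
                              "x": s.positions[0, 0]}])
        x = rec.column("x") - 3.0
        sigma = np.sqrt(R_GAS * 300.0 / k)
        assert kstest(x / sigma, "norm").pvalue > 0.01

    def test_blowup_detection(self, polymer_ff):
        pos = np.array([[1.0, 1.0, 1.0], [1.001, 1.0, 1.0]])
        st = SystemState(pos, np.zeros_like(pos), np.full(3, 6.0),
                         np.zeros(2, dtype=np.int64), Topology.empty(2),
                         rng=np.random.default_rng(0))
        spec = IntegratorSpec(dt=0.05)  # huge step on a hard overlap
        with pytest.raises(RuntimeError):
            for _ in range(200):
                langevin_step(st, polymer_ff, [], spec)


class TestBarostatAndMinimize:
    def test_mc_barostat_reaches_target_pressure(self):
        # supercritical LJ fluid (T* = 1.66): single phase, so the
        # virial-route pressure must match the barostat target without
        # coexistence ambiguity
        sc = Species("S", 0.35, 1.5, 18.0, "water")
        ff = build_forcefield([sc], cutoff=0.9)
        n_side, edge = 6, 2.2
        g = (np.arange(n_side) + 0.5) * edge / n_side
        pos = np.stack(np.meshgrid(g, g, g, indexing="ij"),
                       -1).reshape(-1, 3)
        n = len(pos)
        st = SystemState(pos, np.zeros_like(pos), np.full(3, edge),
                         np.zeros(n, dtype=np.int64), Topology.empty(n),
                         rng=np.random.default_rng(1))
        draw_maxwell_velocities(st, ff, 300.0)
        minimize(st, ff, max_steps=150, tol=300.0)
        target = 500.0  # bar
        ispec = IntegratorSpec(barostat=MCBarostat(target, 10, 0.01))
        run_segment(st, ff, [], ispec, 5000)
        rec = run_segment(st, ff, [], ispec, 10000, observer_stride=50,
                          observers=[lambda s, t: {
                              "P": virial_pressure(s, ff, t)}])
        p = rec.column("P")
        blocks = np.array([b.mean() for b in np.array_split(p, 6)])
        sem = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(p.mean() - target) < max(4 * sem, 100.0)

    def test_minimize_descends_and_respects_tolerance(self, chain8,
                                                      polymer_ff):
        e0, _ = total_energy_forces(chain8, polymer_ff)
        e_final = minimize(chain8, polymer_ff, max_steps=300, tol=10.0)
        assert e_final <= e0["potential"] + 1e-12

    def test_minimal_dimer_unchanged(self, polymer_ff):
        rmin = 2 ** (1 / 6) * 0.4
        pos = np.array([[3.0, 3.0, 3.0], [3.0 + rmin, 3.0, 3.0]])
        st = SystemState(pos, np.zeros_like(pos), np.full(3, 6.0),
                         np.zeros(2, dtype=np.int64), Topology.empty(2))
        minimize(st, polymer_ff, max_steps=100, tol=1e-3)
        assert np.allclose(st.positions, pos, atol=1e-6)

    def test_softcore_overlap_relaxes(self):
        p = default_polymer_species()
        w = Species("W", 0.35, 0.65, 18.0, "water")
        ff = build_forcefield([p, w], softcore_polymer_solvent=True)
        ff = ff.with_lambda(0.5)
        pos = np.array([[3.0, 3.0, 3.0], [3.0, 3.0, 3.05]])
        st = SystemState(pos, np.zeros_like(pos), np.full(3, 6.0),
                         np.array([0, 1], dtype=np.int64),
                         Topology.empty(2))
        e = minimize(st, ff, max_steps=200, tol=1.0)
        assert np.isfinite(e)
        assert e < 1.0
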