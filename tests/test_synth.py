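"""Synthetic mixtures, analytic-PMF samplers, the Widom oracle and
conformer generation."""

import numpy as np
import pytest
from scipy.stats import chisquare

from cononsol.forcefield import R_GAS, Species, build_forcefield
from cononsol.mdengine import (IntegratorSpec, PositionRestraint,
                               compute_rg, draw_maxwell_velocities,
                               run_segment)
from cononsol.synth import (AnalyticPMFSpec, ReducedSolventSpec,
                            analytic_collapse_dg, build_mixture,
                            build_wall_slab, double_well_with_dg,
                            ethanol_like_spec, make_conformers,
                            matched_solvent_count, molecule_volume,
                            sample_biased_rg, split_composition,
                            widom_insertion_oracle)
from cononsol.umbrella import UmbrellaWindow

RT = R_GAS * 300.0


class TestComposition:
    @pytest.mark.parametrize("n, x, expected", [
        (500, 0.1, (450, 50)),
        (400, 0.25, (300, 100)),
        (400, 0.0, (400, 0)),
        (400, 1.0, (0, 400)),
    ])
    def test_largest_remainder_rounding(self, n, x, expected):
        assert split_composition(n, x) == expected

    def test_matched_count_decreases_with_bulkier_cosolvent(self):
        spec = ReducedSolventSpec()
        n0 = matched_solvent_count(spec, 0.0, 450)
        n5 = matched_solvent_count(spec, 0.5, 450)
        assert n0 == 450
        assert n5 < n0

    def test_molecule_volume_union(self):
        v1 = molecule_volume(0.4)
        # two fully separated sites: twice the single volume
        assert molecule_volume(0.4, 2, bond=0.4) == pytest.approx(2 * v1)
        # coincident sites: back to one sphere
        assert molecule_volume(0.4, 2, bond=0.0) == pytest.approx(v1)


class TestBuildMixture:
    spec = ReducedSolventSpec()

    def test_pure_fluids(self):
        st, _, idx = build_mixture(self.spec, 0.0, 60, 2.2, seed=1)
        assert np.all(st.species_index == idx["W"])
        st, _, idx = build_mixture(self.spec, 1.0, 60, 2.4, seed=1)
        assert np.all(st.species_index == idx["A"])

    def test_composition_rounding(self):
        st, _, idx = build_mixture(self.spec, 0.25, 80, 2.4, seed=2)
        assert (st.species_index == idx["A"]).sum() == 20

    def test_determinism(self):
        a, _, _ = build_mixture(self.spec, 0.3, 50, 2.2, seed=9)
        b, _, _ = build_mixture(self.spec, 0.3, 50, 2.2, seed=9)
        assert np.array_equal(a.positions, b.positions)

    def test_two_site_alcohol_bonded(self):
        spec = ethanol_like_spec()
        st, _, idx = build_mixture(spec, 0.5, 40, 2.4, seed=3)
        bonds = st.topology.bonds
        assert len(bonds) == 20
        d = np.linalg.norm(st.positions[bonds[:, 0]]
                           - st.positions[bonds[:, 1]], axis=1)
        assert np.allclose(d, spec.alcohol_bond, atol=1e-9)

    def test_impossible_density_raises(self):
        with pytest.raises(RuntimeError, match="box too small"):
            build_mixture(self.spec, 0.0, 5000, 2.0, seed=1)

    def test_no_hard_overlaps(self):
        st, ff, _ = build_mixture(self.spec, 0.3, 60, 2.2, seed=4)
        d = st.positions[:, None, :] - st.positions[None, :, :]
        d -= st.box * np.rint(d / st.box)
        r = np.sqrt((d * d).sum(axis=2))
        np.fill_diagonal(r, np.inf)
        assert r.min() > 0.2


class TestBiasedSampling:
    def test_harmonic_times_harmonic_is_gaussian(self):
        # w* = kw/2 (x-c)^2 with bias kb/2 (x-r0)^2: product Gaussian
        kw, c = 800.0, 0.8
        kb, r0 = 1200.0, 0.9
        pmf = AnalyticPMFSpec(form="harmonic", k_harm=kw, center_harm=c,
                              domain=(0.3, 1.4))
        win = UmbrellaWindow(rg0=r0, k_b=kb)
        x = sample_biased_rg(pmf, win, 60000, seed=12)
        mean_ref = (kw * c + kb * r0) / (kw + kb)
        var_ref = RT / (kw + kb)
        assert x.mean() == pytest.approx(mean_ref, abs=3e-4)
        assert x.var() == pytest.approx(var_ref, rel=0.03)

    def test_stiff_bias_collapses_to_target(self):
        pmf = AnalyticPMFSpec()
        win = UmbrellaWindow(rg0=0.77, k_b=1e9)
        x = sample_biased_rg(pmf, win, 1000, seed=3)
        assert np.all(np.abs(x - 0.77) < 1e-3)

    def test_histogram_matches_target_density(self):
        pmf = AnalyticPMFSpec()
        win = UmbrellaWindow(rg0=0.7, k_b=500.0)
        n = 10000
        x = sample_biased_rg(pmf, win, n, seed=77)
        edges = np.linspace(0.4, 1.1, 36)
        obs, _ = np.histogram(x, bins=edges)
        grid = np.linspace(0.35, 1.35, 4001)
        dens = np.exp(-(pmf(grid)
                        + 0.5 * win.k_b * (grid - win.rg0) ** 2) / RT)
        cdf = np.concatenate([[0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        probs = np.diff(np.interp(edges, grid, cdf))
        keep = probs * n >= 5
        stat, p = chisquare(obs[keep], probs[keep] / probs[keep].sum()
                            * obs[keep].sum())
        assert p > 0.01

    def test_prescribed_two_state_gap(self):
        for target in (-3.0, 1.5):
            spec = double_well_with_dg(target)
            got = analytic_collapse_dg(spec, 0.7, 300.0, spec.domain)
            assert got == pytest.approx(target, abs=1e-8)


class TestWidomOracle:
    def test_ideal_gas_is_zero(self):
        ghost = Species("G", 0.35, 0.65, 18.0, "polymer")
        ideal = Species("I", 0.35, 0.0, 18.0, "water")
        ff = build_forcefield([ghost, ideal], wca_polymer_solvent=True)
        # epsilon_mix = sqrt(0.65 * 0) = 0: every insertion costs 0
        rng = np.random.default_rng(5)
        frames = [rng.random((40, 3)) * 2.0 for _ in range(4)]
        sp = np.ones(40, dtype=np.int64)
        dg, err = widom_insertion_oracle(frames, np.full(3, 2.0), sp, ff,
                                         0, 4000, seed=8)
        assert dg == pytest.approx(0.0, abs=1e-12)

    def test_hard_wall_limit_free_volume(self):
        # enormous epsilon makes insertion binary: dG = -RT ln(f_free)
        ghost = Species("G", 0.3, 1e8, 18.0, "polymer")
        wall = Species("X", 0.3, 1e8, 18.0, "water")
        ff = build_forcefield([ghost, wall], wca_polymer_solvent=True)
        g = (np.arange(3) + 0.5) * (2.1 / 3)
        lat = np.stack(np.meshgrid(g, g, g), -1).reshape(-1, 3)
        box = np.full(3, 2.1)
        sp = np.ones(len(lat), dtype=np.int64)
        dg, _ = widom_insertion_oracle([lat], box, sp, ff, 0, 200000,
                                       seed=9)
        # independent free-volume estimate on a dense grid
        m = 60
        gg = (np.arange(m) + 0.5) * (2.1 / m)
        pts = np.stack(np.meshgrid(gg, gg, gg, indexing="ij"),
                       -1).reshape(-1, 3)
        d = pts[:, None, :] - lat[None, :, :]
        d -= box * np.rint(d / box)
        rmin = 2 ** (1 / 6) * 0.3
        free = ((d ** 2).sum(-1).min(1) > rmin ** 2).mean()
        assert dg == pytest.approx(-RT * np.log(free), abs=0.25)

    def test_determinism(self):
        ghost = Species("G", 0.35, 0.65, 18.0, "polymer")
        w = Species("W", 0.35, 0.65, 18.0, "water")
        ff = build_forcefield([ghost, w], wca_polymer_solvent=True)
        rng = np.random.default_rng(5)
        frames = [rng.random((30, 3)) * 2.0]
        sp = np.ones(30, dtype=np.int64)
        a = widom_insertion_oracle(frames, np.full(3, 2.0), sp, ff, 0,
                                   2000, seed=3)
        b = widom_insertion_oracle(frames, np.full(3, 2.0), sp, ff, 0,
                                   2000, seed=3)
        assert a == b


class TestConformers:
    @pytest.mark.parametrize("kind, lo, hi", [
        ("coil", 0.95, 1.05),
        ("globule", 0.627, 0.693),
    ])
    def test_rg_band(self, kind, lo, hi, coil32, globule32):
        conf = coil32 if kind == "coil" else globule32
        rg = compute_rg(conf.positions, np.arange(32))
        assert lo <= rg <= hi

    def test_bond_integrity(self, coil32, globule32):
        for conf in (coil32, globule32):
            b = conf.topology.bonds
            d = np.linalg.norm(conf.positions[b[:, 0]]
                               - conf.positions[b[:, 1]], axis=1)
            assert np.all(d < 1.2 * 0.4)

    def test_generator_purity(self):
        a = make_conformers(16, "coil", seed=5)
        b = make_conformers(16, "coil", seed=5)
        assert np.array_equal(a.positions, b.positions)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_conformers(16, "rod", seed=1)


class TestSurfactantPremise:
    def test_amphiphile_enriches_at_repulsive_wall(self):
        """The reduced model's core asymmetry: at a purely repulsive
        wall the alcohol mole fraction in the contact layer exceeds the
        bulk fraction."""
        spec = ReducedSolventSpec()
        x_bulk = 0.2
        st, ff, idx, wall = build_wall_slab(spec, x_bulk, 140, 2.4,
                                            seed=6)
        restr = PositionRestraint(
            k_pr=1e5, reference_positions=st.positions[wall].copy(),
            selection=wall)
        draw_maxwell_velocities(st, ff, 300.0)
        from cononsol.mdengine import minimize
        minimize(st, ff, [restr], max_steps=200, tol=300.0)
        ispec = IntegratorSpec()
        run_segment(st, ff, [restr], ispec, 3000)
        n_w = n_a = 0
        rec = run_segment(st, ff, [restr], ispec, 9000,
                          observer_stride=150,
                          observers=[lambda s, t: {
                              "pos": s.positions.copy()}])
        from cononsol.solvation import first_shell_counts
        for row in rec.rows:
            w, a = first_shell_counts(row["pos"], st.box,
                                      st.species_index,
                                      st.topology.mol_id, wall, idx,
                                      shell_cutoff=0.5)
            n_w += w
            n_a += a
        frac_shell = n_a / (n_a + n_w)
        assert frac_shell > x_bulk
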