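"""Synthetic inputs and oracle fixtures.

This module generates everything the pipeline consumes:

* a *reduced* binary solvent — one-site "water-like" particles plus a
  one-site ("methanol-like") or two-site ("ethanol-like") amphiphile —
  whose size and cohesion asymmetry makes the cosolvent surface-active
  at a repulsive (hydrophobic) interface.  This stands in for atomistic
  water/alcohol models, which are out of desk-scale reach; the
  surfactant mechanism under study needs interfacial adsorption
  asymmetry, which the reduced model is tuned to exhibit (see
  docs/methods.md for the calibration reasoning);
* biased radius-of-gyration samples drawn from analytic free-energy
  profiles, the ground truth for validating WHAM;
* a Widom test-particle insertion estimator, the independent oracle for
  the cavity thermodynamic integration;
* polymer conformers (coil / globule) at prescribed R_g, produced by
  restrained sampling of the actual bonded chain.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import quad
from scipy.optimize import brentq

from .forcefield import (ForceFieldTable, LambdaScaling, R_GAS, Species,
                         build_forcefield, default_polymer_species)
from .mdengine import (IntegratorSpec, RgRestraint, SystemState,
                       Topology, compute_rg, derive_seed,
                       draw_maxwell_velocities, minimize, run_segment)

# ---------------------------------------------------------------------------
# reduced solvent model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReducedSolventSpec:
    """A coarse water + amphiphile mixture.

    The water-like particle is small with a high cohesive-energy
    density (ε/σ³ ≈ 70 kJ·mol⁻¹·nm⁻³); the alcohol-like particle is
    larger with a similar well depth but a much lower cohesive density
    (≈ 29), so it costs the mixture less to place it at an interface —
    the microscopic premise of its surfactant-like behaviour.  Both
    species are kept comfortably liquid at 300 K (ε/RT ≈ 1) so the
    mixture stays a miscible liquid rather than demixing or forming
    vapour pockets.  ``cross_eps_scale`` further tunes the
    water–alcohol attraction around Lorentz–Berthelot (< 1 weakens
    mixing).  ``alcohol_sites`` = 1 gives the "methanol-like"
    cosolvent, 2 the bonded "ethanol-like" dimer.
    """

    water: Species = field(default_factory=lambda: Species(
        "W", sigma=0.35, epsilon=3.0, mass=18.0, role="water"))
    alcohol_site: Species = field(default_factory=lambda: Species(
        "A", sigma=0.45, epsilon=2.6, mass=32.0, role="alcohol"))
    alcohol_sites: int = 1
    alcohol_bond: float = 0.25        # nm, for the 2-site amphiphile
    cross_eps_scale: float = 1.00     # water–alcohol ε knob
    cutoff: float = 0.9               # nm; the reduced fluid is short-ranged

    def __post_init__(self) -> None:
        if self.alcohol_site.sigma < self.water.sigma:
            raise ValueError(
                "alcohol site must be at least water-sized (the size "
                "asymmetry drives preferential adsorption)")
        if self.alcohol_sites not in (1, 2):
            raise ValueError("alcohol_sites must be 1 or 2")


def ethanol_like_spec(**kw) -> ReducedSolventSpec:
    """Two-site amphiphile variant of the reduced solvent."""
    return ReducedSolventSpec(
        alcohol_site=Species("E", sigma=0.40, epsilon=2.2, mass=23.0,
                             role="alcohol"),
        alcohol_sites=2, **kw)


def molecule_volume(species_sigma: float, sites: int = 1,
                    bond: float = 0.0) -> float:
    """Effective molecular volume (nm³) from site radii σ/2; for the
    2-site molecule the sphere-union volume (overlap lens removed)."""
    r = species_sigma / 2.0
    v1 = 4.0 / 3.0 * np.pi * r ** 3
    if sites == 1:
        return v1
    d = min(bond, 2 * r)
    lens = np.pi * (4 * r + d) * (2 * r - d) ** 2 / 12.0
    return 2 * v1 - lens


def matched_solvent_count(spec: ReducedSolventSpec, x_alcohol: float,
                          n_reference: int) -> int:
    """Solvent molecule count at composition X that keeps the packing
    fraction equal to that of ``n_reference`` pure-water molecules.

    The campaign samples different compositions in the same box; at
    fixed particle number the bulkier amphiphile would raise the
    packing fraction and with it the cavity work, which would confound
    the composition trend.  Matching packing fractions through ideal
    mixing of molecular volumes is the desk-scale stand-in for the
    isobaric condition under which compositions are compared.
    """
    v_w = molecule_volume(spec.water.sigma)
    v_a = molecule_volume(spec.alcohol_site.sigma, spec.alcohol_sites,
                          spec.alcohol_bond)
    v_bar = (1.0 - x_alcohol) * v_w + x_alcohol * v_a
    return int(round(n_reference * v_w / v_bar))


def split_composition(n_total: int, x_alcohol: float) -> tuple[int, int]:
    """(n_water, n_alcohol) by largest-remainder rounding of X·N."""
    if not 0.0 <= x_alcohol <= 1.0:
        raise ValueError("x_alcohol must be in [0, 1]")
    n_alc = int(round(x_alcohol * n_total))
    return n_total - n_alc, n_alc


def mixture_forcefield(spec: ReducedSolventSpec,
                       polymer: Species | None = None,
                       scaling: LambdaScaling | None = None,
                       wca_polymer_solvent: bool = False,
                       softcore_polymer_solvent: bool = False,
                       ) -> tuple[ForceFieldTable, dict]:
    """Interaction table for (polymer +) reduced solvent.

    Returns the table and a species-index map ``{"P": 0, "W": i, "A": j}``
    (polymer key absent for neat solvent).  The water–alcohol cross ε is
    rescaled by the spec's ``cross_eps_scale`` after Lorentz–Berthelot
    mixing.
    """
    species = []
    index = {}
    if polymer is not None:
        index["P"] = len(species)
        species.append(polymer)
    index["W"] = len(species)
    species.append(spec.water)
    index["A"] = len(species)
    species.append(spec.alcohol_site)
    ff = build_forcefield(species, scaling=scaling,
                          wca_polymer_solvent=wca_polymer_solvent,
                          softcore_polymer_solvent=softcore_polymer_solvent,
                          cutoff=spec.cutoff)
    iw, ia = index["W"], index["A"]
    ff.epsilon[iw, ia] *= spec.cross_eps_scale
    ff.epsilon[ia, iw] *= spec.cross_eps_scale
    return ff, index


def _insert_molecules(rng: np.random.Generator, existing: np.ndarray,
                      existing_sigma: np.ndarray, box: np.ndarray,
                      n_mol: int, sites: int, sigma: float, bond: float,
                      min_scale: float = 0.80,
                      max_attempts_per_mol: int = 2000) -> np.ndarray:
    """Random insertion with hard-overlap rejection (minimum image)."""
    placed = list(existing)
    placed_sigma = list(existing_sigma)
    out = []
    for _ in range(n_mol):
        for attempt in range(max_attempts_per_mol):
            first = rng.random(3) * box
            if sites == 2:
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                mol = np.stack([first, first + bond * u])
            else:
                mol = first[None, :]
            if placed:
                arr = np.asarray(placed)
                sig = np.asarray(placed_sigma)
                ok = True
                for site in mol:
                    d = site - arr
                    d -= box * np.rint(d / box)
                    r = np.sqrt((d * d).sum(axis=1))
                    if np.any(r < min_scale * 0.5 * (sig + sigma)):
                        ok = False
                        break
                if not ok:
                    continue
            for site in mol:
                placed.append(site)
                placed_sigma.append(sigma)
                out.append(site)
            break
        else:
            raise RuntimeError(
                "solvent insertion failed: box too small for the "
                "requested particle count; increase the box or lower N")
    return np.asarray(out).reshape(-1, 3)


def _lattice_sites(rng: np.random.Generator, existing: np.ndarray,
                   box: np.ndarray, n_needed: int,
                   clearance: float = 0.33) -> np.ndarray:
    """Shuffled simple-cubic sites at least ``clearance`` from existing
    particles; the grid is refined until enough sites are free.  Used
    for liquid-density systems where random insertion would jam."""
    n_side = max(2, int(np.ceil(n_needed ** (1.0 / 3.0))))
    for _ in range(8):
        axes = [(np.arange(n_side) + 0.5) * box[d] / n_side
                for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        sites = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        if len(existing):
            d = sites[:, None, :] - existing[None, :, :]
            d -= box * np.rint(d / box)
            r = np.sqrt((d * d).sum(axis=2)).min(axis=1)
            sites = sites[r > clearance]
        if len(sites) >= n_needed:
            return sites[rng.permutation(len(sites))[:n_needed]]
        n_side += 1
    raise RuntimeError(
        "lattice placement failed: box too small for the requested "
        "solvent count; increase the box or lower N")


def build_mixture(spec: ReducedSolventSpec, x_alcohol: float, n_total: int,
                  box: float | np.ndarray, seed: int,
                  polymer_state: SystemState | None = None,
                  polymer_species: Species | None = None,
                  scaling: LambdaScaling | None = None,
                  wca_polymer_solvent: bool = False,
                  softcore_polymer_solvent: bool = False,
                  center_polymer: bool = True,
                  placement: str = "random",
                  ) -> tuple[SystemState, ForceFieldTable, dict]:
    """Assemble a (solvated) mixture system.

    ``n_total`` counts solvent *molecules*; the realised composition is
    ``split_composition(n_total, x_alcohol)``.  If ``polymer_state`` is
    given its particles come first and its topology is preserved.
    ``placement`` is ``"random"`` (insertion with overlap rejection;
    fine up to moderate densities) or ``"lattice"`` (shuffled cubic
    lattice start for liquid densities, to be relaxed by minimisation
    and equilibration).  Returns ``(state, forcefield,
    species_index_map)``.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float) * np.ones(3)
    n_w, n_a = split_composition(n_total, x_alcohol)
    polymer = polymer_species
    if polymer_state is not None and polymer is None:
        polymer = default_polymer_species()
    ff, index = mixture_forcefield(
        spec, polymer=polymer if polymer_state is not None else None,
        scaling=scaling, wca_polymer_solvent=wca_polymer_solvent,
        softcore_polymer_solvent=softcore_polymer_solvent)

    if polymer_state is not None:
        pos0 = polymer_state.positions.copy()
        if center_polymer:
            pos0 += 0.5 * box - pos0.mean(axis=0)
        sig0 = np.full(len(pos0), polymer.sigma)
        sp = [np.full(len(pos0), index["P"], dtype=np.int64)]
        bonds = [polymer_state.topology.bonds.copy()]
        angles = [polymer_state.topology.angles.copy()]
        mol = [np.zeros(len(pos0), dtype=np.int64)]
        n_placed = len(pos0)
        mol_count = 1
    else:
        pos0 = np.zeros((0, 3))
        sig0 = np.zeros(0)
        sp, bonds, angles, mol = [], [], [], []
        n_placed = 0
        mol_count = 0

    if placement == "lattice":
        sites = _lattice_sites(rng, pos0, box, n_w + n_a)
        water_pos = sites[:n_w]
        if spec.alcohol_sites == 2 and n_a:
            first = sites[n_w:]
            u = rng.standard_normal((n_a, 3))
            u /= np.linalg.norm(u, axis=1)[:, None]
            alc_pos = np.empty((2 * n_a, 3))
            alc_pos[0::2] = first
            alc_pos[1::2] = first + spec.alcohol_bond * u
        else:
            alc_pos = sites[n_w:]
    elif placement == "random":
        water_pos = _insert_molecules(rng, pos0, sig0, box, n_w, 1,
                                      spec.water.sigma, 0.0)
        all_pos = np.vstack([pos0, water_pos]) if n_w else pos0
        all_sig = np.concatenate([sig0, np.full(n_w, spec.water.sigma)])
        alc_pos = _insert_molecules(rng, all_pos, all_sig, box, n_a,
                                    spec.alcohol_sites,
                                    spec.alcohol_site.sigma,
                                    spec.alcohol_bond)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    all_pos = np.vstack([pos0, water_pos]) if n_w else pos0
    sp.append(np.full(n_w, index["W"], dtype=np.int64))
    mol.append(mol_count + np.arange(n_w, dtype=np.int64))
    mol_count += n_w
    n_placed += n_w
    sp.append(np.full(n_a * spec.alcohol_sites, index["A"], dtype=np.int64))
    mol.append(mol_count + np.repeat(np.arange(n_a, dtype=np.int64),
                                     spec.alcohol_sites))
    if spec.alcohol_sites == 2 and n_a:
        first = n_placed + 2 * np.arange(n_a, dtype=np.int64)
        bonds.append(np.stack([first, first + 1], axis=1))
    positions = np.vstack([all_pos, alc_pos]) if n_a else all_pos
    species_index = np.concatenate(sp)
    bond_arr = (np.vstack(bonds) if bonds else
                np.zeros((0, 2), dtype=np.int64))
    angle_arr = (np.vstack(angles) if angles else
                 np.zeros((0, 3), dtype=np.int64))
    topo = Topology(bond_arr, angle_arr, np.concatenate(mol)
                    if mol else np.zeros(0, dtype=np.int64))
    state = SystemState(positions, np.zeros_like(positions), box,
                        species_index, topo,
                        rng=np.random.default_rng(derive_seed(seed, 1)))
    return state, ff, index


# ---------------------------------------------------------------------------
# polymer chain construction and conformers
# ---------------------------------------------------------------------------

def make_polymer_chain(n_beads: int = 32, r0: float = 0.4,
                       box_edge: float = 20.0) -> SystemState:
    """Straight tangent-bead chain with consecutive bonds and angles."""
    pos = np.zeros((n_beads, 3))
    pos[:, 0] = r0 * np.arange(n_beads)
    pos += box_edge / 2.0 - pos.mean(axis=0)
    idx = np.arange(n_beads, dtype=np.int64)
    bonds = np.stack([idx[:-1], idx[1:]], axis=1)
    angles = np.stack([idx[:-2], idx[1:-1], idx[2:]], axis=1)
    topo = Topology(bonds, angles, np.zeros(n_beads, dtype=np.int64))
    return SystemState(pos, np.zeros_like(pos), np.full(3, box_edge),
                       np.zeros(n_beads, dtype=np.int64), topo)


#: most probable R_g of the 32-bead chain's two basins in this reduced
#: model.  The coil mode follows the published selection target
#: (1.0 nm).  The atomistic protocol's globule target of 0.5 nm lies
#: *below* the dense-packing limit of 32 beads with σ_p = 0.4 nm
#: (an FCC cluster at tangent spacing already has R_g = 0.56 nm, and the
#: relaxed amorphous globule sits near LJ-minimum spacing), so the
#: package uses the model's compact-basin mode instead; see
#: docs/methods.md.
COIL_RG_32 = 1.0       # nm
GLOBULE_RG_32 = 0.66   # nm


def make_conformers(n_beads: int, kind: str, seed: int,
                    temperature: float = 300.0,
                    target_rg: float | None = None) -> SystemState:
    """Coil or globule conformer at a prescribed R_g (±5 %).

    The chain (bonds, angles, full LJ bead–bead interactions) is
    steered from a straight start by a moving harmonic R_g restraint —
    the target is ramped down in small decrements, then the chain is
    equilibrated under the stiff production restraint
    (k_b = 20000 kJ·mol⁻¹·nm⁻², R_g fluctuation sqrt(RT/k_b) ≈
    0.011 nm), so the ±5 % band is hit by construction.  Default
    targets for N = 32 are ``COIL_RG_32`` and ``GLOBULE_RG_32``; other
    lengths scale as N^0.588 (coil) and N^(1/3) (globule).
    """
    if kind not in ("coil", "globule"):
        raise ValueError("kind must be 'coil' or 'globule'")
    if target_rg is None:
        if kind == "coil":
            target_rg = COIL_RG_32 * (n_beads / 32.0) ** 0.588
        else:
            target_rg = GLOBULE_RG_32 * (n_beads / 32.0) ** (1.0 / 3.0)
    state = make_polymer_chain(n_beads)
    state.rng = np.random.default_rng(derive_seed(seed, 7))
    ff = build_forcefield([default_polymer_species()],
                          scaling=LambdaScaling(1.0, 1.0))
    sel = np.arange(n_beads)
    spec = IntegratorSpec(dt=0.002, temperature=temperature,
                          friction_time=0.1)
    draw_maxwell_velocities(state, ff, temperature)
    # steering ramp: walk the restraint centre toward the target
    rg = compute_rg(state.positions, sel)
    ramp = np.arange(rg, target_rg, -0.1 if rg > target_rg else 0.1)
    for rg0 in ramp:
        run_segment(state, ff,
                    [RgRestraint(k_b=2000.0, rg0=float(rg0),
                                 selection=sel)], spec, 400)
    stiff = RgRestraint(k_b=20000.0, rg0=target_rg, selection=sel)
    run_segment(state, ff, [stiff], spec, 4000)
    rg = compute_rg(state.positions, sel)
    if abs(rg - target_rg) > 0.05 * target_rg:
        run_segment(state, ff, [stiff], spec, 8000)
        rg = compute_rg(state.positions, sel)
    if abs(rg - target_rg) > 0.05 * target_rg:
        raise RuntimeError(
            f"conformer generation missed target R_g {target_rg:.3f} "
            f"(got {rg:.3f}); the target may be below the chain's "
            "dense-packing limit for this bead size")
    state.velocities[:] = 0.0
    return state


# ---------------------------------------------------------------------------
# analytic PMFs and biased R_g sampling (WHAM ground truth)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyticPMFSpec:
    """Analytic free-energy profile w*(ξ) on a finite ξ-domain.

    forms: ``double_well`` (two Gaussian wells, optional linear tilt),
    ``harmonic``, ``uniform``, ``tabulated``.
    """

    form: str = "double_well"
    centers: tuple[float, float] = (0.55, 1.0)
    depths: tuple[float, float] = (6.0, 6.0)      # kJ/mol
    widths: tuple[float, float] = (0.07, 0.09)    # nm
    tilt: float = 0.0                             # kJ/mol/nm, about 0.7 nm
    k_harm: float = 0.0
    center_harm: float = 0.7
    domain: tuple[float, float] = (0.35, 1.35)
    table: tuple = ()

    def __call__(self, xi):
        xi = np.asarray(xi, dtype=float)
        if self.form == "uniform":
            return np.zeros_like(xi)
        if self.form == "harmonic":
            return 0.5 * self.k_harm * (xi - self.center_harm) ** 2
        if self.form == "tabulated":
            gx, gw = np.asarray(self.table[0]), np.asarray(self.table[1])
            return np.interp(xi, gx, gw)
        if self.form == "double_well":
            (c1, c2), (a1, a2), (s1, s2) = (self.centers, self.depths,
                                            self.widths)
            w = (-a1 * np.exp(-0.5 * ((xi - c1) / s1) ** 2)
                 - a2 * np.exp(-0.5 * ((xi - c2) / s2) ** 2)
                 + self.tilt * (xi - 0.7))
            return w
        raise ValueError(f"unknown PMF form {self.form!r}")


def analytic_collapse_dg(pmf, rg_cut: float, temperature: float,
                         domain: tuple[float, float]) -> float:
    """High-resolution quadrature of the two-state ratio (independent
    oracle for the tabulated estimator): ΔG = −RT ln(∫_low / ∫_high) of
    e^{−w/RT} split at ``rg_cut``."""
    rt = R_GAS * temperature
    lo, hi = domain
    num, _ = quad(lambda x: np.exp(-pmf(x) / rt), lo, rg_cut, limit=200)
    den, _ = quad(lambda x: np.exp(-pmf(x) / rt), rg_cut, hi, limit=200)
    return -rt * np.log(num / den)


def double_well_with_dg(dg_target: float, rg_cut: float = 0.7,
                        temperature: float = 300.0,
                        base: AnalyticPMFSpec | None = None
                        ) -> AnalyticPMFSpec:
    """Double-well profile whose two-state free energy equals
    ``dg_target`` exactly (linear tilt solved by root finding against
    the quadrature oracle)."""
    base = base or AnalyticPMFSpec()

    def gap(tilt):
        spec = AnalyticPMFSpec(form="double_well", centers=base.centers,
                               depths=base.depths, widths=base.widths,
                               tilt=tilt, domain=base.domain)
        return analytic_collapse_dg(spec, rg_cut, temperature,
                                    base.domain) - dg_target

    tilt = brentq(gap, -80.0, 80.0, xtol=1e-10)
    return AnalyticPMFSpec(form="double_well", centers=base.centers,
                           depths=base.depths, widths=base.widths,
                           tilt=tilt, domain=base.domain)


def sample_biased_rg(pmf, window, n: int, seed: int,
                     temperature: float = 300.0,
                     domain: tuple[float, float] | None = None,
                     grid_points: int = 4001) -> np.ndarray:
    """Draw ξ samples from ∝ exp(−(w*(ξ) + V_window(ξ))/RT).

    Inverse-CDF sampling on a fine grid; ``window`` provides ``rg0``
    and ``k_b`` (any object with those attributes, e.g.
    :class:`~cononsol.umbrella.UmbrellaWindow`).
    """
    rt = R_GAS * temperature
    if domain is None:
        domain = getattr(pmf, "domain", (0.35, 1.35))
    grid = np.linspace(domain[0], domain[1], grid_points)
    w = np.asarray(pmf(grid), dtype=float)
    bias = 0.5 * window.k_b * (grid - window.rg0) ** 2
    logp = -(w + bias) / rt
    logp -= logp.max()
    p = np.exp(logp)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1])
                                           * np.diff(grid))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return np.interp(u, cdf, grid)


# ---------------------------------------------------------------------------
# Widom test-particle insertion oracle
# ---------------------------------------------------------------------------

@njit(cache=True)
def _insertion_du(point, pos, box, sp, sigma, eps, mode, cutoff, ghost_sp):
    """ΔU of a ghost particle at `point` against all particles."""
    du = 0.0
    cutoff2 = cutoff * cutoff
    two_sixth = 2.0 ** (1.0 / 6.0)
    for j in range(pos.shape[0]):
        m = mode[ghost_sp, sp[j]]
        if m == 3:
            continue
        dx = point[0] - pos[j, 0]
        dy = point[1] - pos[j, 1]
        dz = point[2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        s = sigma[ghost_sp, sp[j]]
        e = eps[ghost_sp, sp[j]]
        if m == 0:
            if r2 < cutoff2:
                if r2 < 1e-12:
                    return 1e30
                sr6 = (s * s / r2) ** 3
                du += 4.0 * e * (sr6 * sr6 - sr6)
        else:  # WCA or soft-core at full coupling: plain WCA energy
            rmin2 = (two_sixth * s) ** 2
            if r2 < rmin2:
                if r2 < 1e-12:
                    return 1e30
                sr6 = (s * s / r2) ** 3
                du += 4.0 * e * (sr6 * sr6 - sr6) + e
    return du


def widom_insertion_oracle(frames: list[np.ndarray], box: np.ndarray,
                           species_index: np.ndarray, ff: ForceFieldTable,
                           ghost_species: int, n_insertions: int, seed: int,
                           temperature: float = 300.0
                           ) -> tuple[float, float]:
    """Brute-force excess chemical potential of a ghost particle.

    μ_ex = −RT ln⟨e^{−βΔU}⟩ over uniform random insertions into frozen
    configurations.  The standard error comes from treating each frame's
    insertion average as one block.  Valid for small cavities only: the
    estimator degenerates when e^{−βΔU} almost never hits.
    """
    rt = R_GAS * temperature
    rng = np.random.default_rng(seed)
    per_frame = max(1, n_insertions // max(1, len(frames)))
    box = np.asarray(box, dtype=float)
    frame_means = []
    for pos in frames:
        points = rng.random((per_frame, 3)) * box
        acc = 0.0
        for p in points:
            du = _insertion_du(p, pos, box, species_index, ff.sigma,
                               ff.epsilon, ff.mode, ff.cutoff, ghost_species)
            acc += np.exp(-du / rt) if du < 1e29 else 0.0
        frame_means.append(acc / per_frame)
    means = np.asarray(frame_means)
    mhat = means.mean()
    if mhat <= 0:
        raise RuntimeError("Widom estimator collapsed: no accepted "
                           "insertions (cavity too large for this oracle)")
    dg = -rt * np.log(mhat)
    if len(means) > 1:
        sem = means.std(ddof=1) / np.sqrt(len(means))
        stderr = rt * sem / mhat
    else:
        stderr = np.inf
    return float(dg), float(stderr)


# ---------------------------------------------------------------------------
# slab fixture: the interfacial-adsorption premise
# ---------------------------------------------------------------------------

def calibrate_mixture_box(spec: ReducedSolventSpec, x_alcohol: float,
                          n_mol: int, seed: int,
                          temperature: float = 300.0,
                          pressure_bar: float = 1.01325,
                          box_start: float = 3.0,
                          n_steps: int = 6000) -> float:
    """Equilibrium box edge (nm) of the neat solvent mixture at the
    target pressure, from an MC-barostat NPT run averaged over its
    second half.

    Campaign TI runs use this *calibrated, fixed* box (plus the
    conformer's cavity volume) instead of per-run NPT: a per-run box
    realisation adds ~1 % density scatter, which couples to the cavity
    work far more strongly than any remaining finite-size effect.
    """
    from .mdengine import MCBarostat

    state, ff, _ = build_mixture(spec, x_alcohol, n_mol, box_start, seed,
                                 placement="lattice")
    draw_maxwell_velocities(state, ff, temperature)
    minimize(state, ff, max_steps=200, tol=300.0)
    ispec = IntegratorSpec(temperature=temperature,
                           barostat=MCBarostat(pressure_bar, 10, 0.01))
    run_segment(state, ff, [], ispec, n_steps // 2)
    rec = run_segment(state, ff, [], ispec, n_steps - n_steps // 2,
                      observer_stride=20,
                      observers=[lambda s, t: {"L": float(s.box[0])}])
    return float(np.mean(rec.column("L")))


def union_volume(positions: np.ndarray, radius: float, seed: int = 0,
                 n_points: int = 40000) -> float:
    """Monte-Carlo union volume (nm³) of equal spheres at ``positions``
    — the solvent-excluded cavity volume of a conformer."""
    rng = np.random.default_rng(seed)
    lo = positions.min(axis=0) - radius
    hi = positions.max(axis=0) + radius
    pts = lo + rng.random((n_points, 3)) * (hi - lo)
    d2 = ((pts[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)
    inside = (d2.min(axis=1) <= radius * radius)
    return float(np.prod(hi - lo) * inside.mean())


def build_wall_slab(spec: ReducedSolventSpec, x_alcohol: float,
                    n_solvent: int, box_edge: float, seed: int,
                    wall_spacing: float = 0.35
                    ) -> tuple[SystemState, ForceFieldTable, dict,
                               np.ndarray]:
    """Solvent mixture against a frozen repulsive (WCA) bead wall.

    The wall is a square lattice of polymer-species beads spanning one
    box face; solvent interacts with it purely repulsively.  Returns
    (state, ff, index, wall_selection); the wall is meant to be held by
    a stiff position restraint during sampling.  Used to verify the
    reduced model's premise: the amphiphile enriches at a hydrophobic
    interface relative to bulk.
    """
    n_side = int(np.floor(box_edge / wall_spacing))
    xs = (np.arange(n_side) + 0.5) * box_edge / n_side
    gx, gy = np.meshgrid(xs, xs)
    wall = np.stack([gx.ravel(), gy.ravel(),
                     np.full(gx.size, 0.5 * wall_spacing)], axis=1)
    idx = np.arange(len(wall), dtype=np.int64)
    topo = Topology(np.zeros((0, 2), dtype=np.int64),
                    np.zeros((0, 3), dtype=np.int64),
                    np.zeros(len(wall), dtype=np.int64))
    wall_state = SystemState(wall, np.zeros_like(wall),
                             np.full(3, box_edge),
                             np.zeros(len(wall), dtype=np.int64), topo)
    state, ff, index = build_mixture(
        spec, x_alcohol, n_solvent, box_edge, seed,
        polymer_state=wall_state, wca_polymer_solvent=True,
        center_polymer=False)
    return state, ff, index, idx
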