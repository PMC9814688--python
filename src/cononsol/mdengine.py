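"""Stochastic dynamics engine: Langevin (BAOAB leapfrog) propagation of
bead systems under orthorhombic periodic boundaries, with the harmonic
radius-of-gyration restraint used for umbrella sampling and per-particle
position restraints used to freeze conformations during cavity TI.

Coordinates are stored *unwrapped*; the minimum-image convention makes
pair interactions independent of wrapping as long as every box edge is
at least twice the interaction cutoff (asserted).  Keeping the polymer
unwrapped means R_g and its restraint force are always well defined —
a molecule is never broken across periodic images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .forcefield import (ForceFieldTable, PairMode, R_GAS, TWO_SIXTH,
                         BAR_TO_KJ_PER_MOL_NM3)

MIN_PAIR_DISTANCE = 1e-4  # nm; overlap guard under full LJ


# ---------------------------------------------------------------------------
# system state and restraints
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Connectivity: bonds (B,2), angles (A,3), molecule ids (N,)."""

    bonds: np.ndarray
    angles: np.ndarray
    mol_id: np.ndarray

    @staticmethod
    def empty(n: int) -> "Topology":
        return Topology(np.zeros((0, 2), dtype=np.int64),
                        np.zeros((0, 3), dtype=np.int64),
                        np.arange(n, dtype=np.int64))


@dataclass
class SystemState:
    positions: np.ndarray          # (N, 3) nm, unwrapped
    velocities: np.ndarray         # (N, 3) nm/ps
    box: np.ndarray                # (3,) nm
    species_index: np.ndarray      # (N,) int
    topology: Topology
    step: int = 0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.velocities) == len(self.species_index) == n):
            raise ValueError("inconsistent array lengths in SystemState")
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)

    def copy(self) -> "SystemState":
        """Deep copy of arrays; the RNG object is shared (reseed via
        ``replace_rng`` for an independent stream)."""
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.box.copy(), self.species_index.copy(),
                           self.topology, self.step, self.rng)

    def replace_rng(self, seed: int) -> "SystemState":
        new = self.copy()
        new.rng = np.random.default_rng(seed)
        return new

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def wrapped_positions(self) -> np.ndarray:
        return self.positions - self.box * np.floor(self.positions / self.box)


@dataclass(frozen=True)
class RgRestraint:
    """Harmonic bias V(R_g) = k_b/2 (R_g − R_g°)² on selected particles."""

    k_b: float
    rg0: float
    selection: np.ndarray

    def __post_init__(self) -> None:
        if self.k_b < 0:
            raise ValueError("k_b must be >= 0")
        if len(self.selection) == 0:
            raise ValueError("selection must be non-empty")


@dataclass(frozen=True)
class PositionRestraint:
    """Per-particle harmonic tether to fixed reference coordinates."""

    k_pr: float
    reference_positions: np.ndarray
    selection: np.ndarray

    def __post_init__(self) -> None:
        if self.k_pr < 0:
            raise ValueError("k_pr must be >= 0")
        if len(self.reference_positions) != len(self.selection):
            raise ValueError("reference/selection length mismatch")


@dataclass(frozen=True)
class MCBarostat:
    pressure_bar: float = 1.0
    interval: int = 25
    max_dlnv: float = 0.02


@dataclass(frozen=True)
class IntegratorSpec:
    dt: float = 0.002            # ps
    temperature: float = 300.0   # K
    friction_time: float = 0.1   # ps (inverse friction constant)
    barostat: MCBarostat | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.friction_time <= 0:
            raise ValueError("friction_time must be > 0")


# ---------------------------------------------------------------------------
# collective variable: radius of gyration
# ---------------------------------------------------------------------------

def compute_rg(positions: np.ndarray, selection: np.ndarray) -> float:
    """Equal-mass radius of gyration of the selected particles.

    R_g = sqrt((1/N) Σ_i |r_i − r_cm|²).  Coordinates must be unwrapped
    (the engine stores them so); callers with wrapped input must unwrap
    first.
    """
    sel = np.asarray(selection)
    if len(sel) < 2:
        raise ValueError("R_g needs at least 2 particles")
    r = positions[sel]
    d = r - r.mean(axis=0)
    return float(np.sqrt((d * d).sum() / len(sel)))


def check_molecule_integrity(state: SystemState) -> None:
    """Raise if any bond is longer than half the shortest box edge."""
    bonds = state.topology.bonds
    if len(bonds) == 0:
        return
    d = state.positions[bonds[:, 0]] - state.positions[bonds[:, 1]]
    lengths = np.linalg.norm(d, axis=1)
    limit = 0.5 * state.box.min()
    if np.any(lengths > limit):
        worst = float(lengths.max())
        raise RuntimeError(
            f"broken molecule: bond length {worst:.3f} nm exceeds half "
            f"the box ({limit:.3f} nm)")


def rg_restraint_energy_forces(positions: np.ndarray, r: RgRestraint
                               ) -> tuple[float, np.ndarray]:
    """Energy and per-particle forces of the harmonic R_g restraint.

    F_i = −k_b (R_g − R_g°) (r_i − r_cm) / (N R_g) on selected
    particles, zero elsewhere; the forces sum to zero by construction.
    """
    rg = compute_rg(positions, r.selection)
    if rg == 0.0 and r.rg0 != 0.0:
        raise ValueError("degenerate R_g gradient: all particles coincide")
    delta = rg - r.rg0
    energy = 0.5 * r.k_b * delta * delta
    forces = np.zeros_like(positions)
    if rg > 0.0:
        sel = np.asarray(r.selection)
        rel = positions[sel] - positions[sel].mean(axis=0)
        forces[sel] = -r.k_b * delta * rel / (len(sel) * rg)
    return energy, forces


# ---------------------------------------------------------------------------
# numba pair/bonded kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pair_kernel(pos, box, sp, sigma, eps, mode, cutoff, lam,
                 sc_alpha, sc_p, sc_sigma6, sc_pair_sigma, excl, forces):
    """O(N²) minimum-image pair loop.

    Returns (E_lj, E_wca, E_sc, dU/dλ, virial, min_lj_r) where virial is
    Σ_pairs F_ij·r_ij and min_lj_r the smallest full-LJ pair distance
    seen (overlap guard handled by the caller).
    """
    n = pos.shape[0]
    e_lj = 0.0
    e_wca = 0.0
    e_sc = 0.0
    dudl = 0.0
    virial = 0.0
    min_lj_r = 1e30
    cutoff2 = cutoff * cutoff
    shift_fac = sc_alpha * (1.0 - lam) ** sc_p
    if sc_p == 1:
        dshift_fac = -sc_alpha
    else:
        dshift_fac = -sc_alpha * sc_p * (1.0 - lam) ** (sc_p - 1)
    for i in range(n):
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            m = mode[sp[i], sp[j]]
            if m == 3:  # EXCLUDED
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            s = sigma[sp[i], sp[j]]
            e = eps[sp[i], sp[j]]
            fr = 0.0  # F/r, so F_vec = fr * r_vec
            if m == 0:  # full LJ, truncated
                if r2 < cutoff2:
                    if r2 < 1e-12:   # exact overlap: flag, let caller raise
                        min_lj_r = 0.0
                        continue
                    r = np.sqrt(r2)
                    if r < min_lj_r:
                        min_lj_r = r
                    sr6 = (s * s / r2) ** 3
                    e_lj += 4.0 * e * (sr6 * sr6 - sr6)
                    fmag = 24.0 * e * (2.0 * sr6 * sr6 - sr6) / r
                    fr = fmag / r
                    virial += fmag * r
            elif m == 1:  # WCA
                rmin2 = (TWO_SIXTH * s) ** 2
                if r2 < rmin2:
                    r = np.sqrt(r2)
                    sr6 = (s * s / r2) ** 3
                    e_wca += 4.0 * e * (sr6 * sr6 - sr6) + e
                    fmag = 24.0 * e * (2.0 * sr6 * sr6 - sr6) / r
                    fr = fmag / r
                    virial += fmag * r
            elif m == 2:  # soft-core-coupled WCA
                r6 = r2 * r2 * r2
                sc6 = (s * s * s * s * s * s) if sc_pair_sigma else sc_sigma6
                rsc = (shift_fac * sc6 + r6) ** (1.0 / 6.0)
                rmin = TWO_SIXTH * s
                if rsc < rmin:
                    sr6 = (s / rsc) ** 6
                    u_wca = 4.0 * e * (sr6 * sr6 - sr6) + e
                    f_wca = 24.0 * e * (2.0 * sr6 * sr6 - sr6) / rsc
                    e_sc += lam * u_wca
                    drsc_dlam = dshift_fac * sc6 / (6.0 * rsc ** 5)
                    dudl += u_wca + lam * (-f_wca) * drsc_dlam
                    if r2 > 0.0:
                        r = np.sqrt(r2)
                        fmag = lam * f_wca * (r ** 5 / rsc ** 5)
                        fr = fmag / r
                        virial += fmag * r
            if fr != 0.0:
                fx = fr * dx
                fy = fr * dy
                fz = fr * dz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
    return e_lj, e_wca, e_sc, dudl, virial, min_lj_r


@njit(cache=True)
def _bonded_kernel(pos, bonds, angles, bond_k, bond_r0,
                   angle_k, theta0, forces):
    """Harmonic bonds and angles; returns (E_bond, E_angle, virial)."""
    e_bond = 0.0
    e_angle = 0.0
    virial = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        delta = r - bond_r0
        e_bond += 0.5 * bond_k * delta * delta
        fmag = -bond_k * delta  # along +r_ij for i
        fr = fmag / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
        virial += fmag * r
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        r1x = pos[i, 0] - pos[j, 0]
        r1y = pos[i, 1] - pos[j, 1]
        r1z = pos[i, 2] - pos[j, 2]
        r2x = pos[k, 0] - pos[j, 0]
        r2y = pos[k, 1] - pos[j, 1]
        r2z = pos[k, 2] - pos[j, 2]
        n1 = np.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
        n2 = np.sqrt(r2x * r2x + r2y * r2y + r2z * r2z)
        c = (r1x * r2x + r1y * r2y + r1z * r2z) / (n1 * n2)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dtheta = theta - theta0
        e_angle += 0.5 * angle_k * dtheta * dtheta
        st = np.sqrt(1.0 - c * c)
        # dV/dtheta / sin(theta); finite limit k*(theta-theta0)/sin ->
        # handled by clamping sin away from zero (theta0 = pi gives a
        # finite limit of the full expression)
        if st < 1e-8:
            st = 1e-8
        coef = angle_k * dtheta / st
        # grad_i cos = (r2/ (n1 n2)) - c * r1 / n1^2 etc.
        gix = r2x / (n1 * n2) - c * r1x / (n1 * n1)
        giy = r2y / (n1 * n2) - c * r1y / (n1 * n1)
        giz = r2z / (n1 * n2) - c * r1z / (n1 * n1)
        gkx = r1x / (n1 * n2) - c * r2x / (n2 * n2)
        gky = r1y / (n1 * n2) - c * r2y / (n2 * n2)
        gkz = r1z / (n1 * n2) - c * r2z / (n2 * n2)
        # F = -dV/dr = -dV/dtheta * dtheta/dcos * grad cos
        #   = (dV/dtheta / sin) * grad cos  (dtheta/dcos = -1/sin)
        forces[i, 0] += coef * gix
        forces[i, 1] += coef * giy
        forces[i, 2] += coef * giz
        forces[k, 0] += coef * gkx
        forces[k, 1] += coef * gky
        forces[k, 2] += coef * gkz
        forces[j, 0] -= coef * (gix + gkx)
        forces[j, 1] -= coef * (giy + gky)
        forces[j, 2] -= coef * (giz + gkz)
    return e_bond, e_angle, virial


def _exclusion_matrix(n: int, bonds: np.ndarray) -> np.ndarray:
    excl = np.zeros((n, n), dtype=np.bool_)
    if len(bonds):
        excl[bonds[:, 0], bonds[:, 1]] = True
        excl[bonds[:, 1], bonds[:, 0]] = True
    return excl


# small content-keyed cache (bond lists are tiny; hashing is cheap
# relative to one force evaluation)
_EXCL_CACHE: dict[tuple, np.ndarray] = {}


def _get_exclusions(state: SystemState) -> np.ndarray:
    key = (state.n_particles, state.topology.bonds.tobytes())
    mat = _EXCL_CACHE.get(key)
    if mat is None:
        if len(_EXCL_CACHE) > 8:
            _EXCL_CACHE.clear()
        mat = _exclusion_matrix(state.n_particles, state.topology.bonds)
        _EXCL_CACHE[key] = mat
    return mat


def total_energy_forces(state: SystemState, ff: ForceFieldTable,
                        restraints: Sequence[object] = ()
                        ) -> tuple[dict, np.ndarray]:
    """Potential energy decomposed by term, and per-particle forces.

    Returns ``(terms, forces)`` where ``terms`` has keys ``lj``, ``wca``,
    ``softcore``, ``bond``, ``angle``, ``restraint_rg``,
    ``restraint_pos``, ``potential`` (total), ``dudl`` (soft-core
    ∂U/∂λ) and ``virial`` (pair+bond Σ F·r, for the pressure).
    """
    if np.min(state.box) < 2.0 * ff.cutoff and np.any(
            ff.mode == int(PairMode.LJ)):
        raise ValueError(
            f"minimum-image requires box edge >= 2*cutoff "
            f"({2 * ff.cutoff:.2f} nm); box = {state.box}")
    forces = np.zeros_like(state.positions)
    excl = _get_exclusions(state)
    e_lj, e_wca, e_sc, dudl, virial, min_lj_r = _pair_kernel(
        state.positions, state.box, state.species_index,
        ff.sigma, ff.epsilon, ff.mode, ff.cutoff, ff.lam,
        ff.softcore.alpha, ff.softcore.p, ff.softcore.sigma_sc ** 6,
        ff.sc_pair_sigma, excl, forces)
    if min_lj_r < MIN_PAIR_DISTANCE:
        raise RuntimeError(
            f"overlapping particles under full LJ: r = {min_lj_r:.2e} nm")
    e_bond, e_angle, bv = _bonded_kernel(
        state.positions, state.topology.bonds, state.topology.angles,
        ff.bond_k, ff.bond_r0, ff.angle_k, ff.angle_theta0, forces)
    virial += bv
    e_rg = 0.0
    e_pos = 0.0
    for rs in restraints:
        if isinstance(rs, RgRestraint):
            e, f = rg_restraint_energy_forces(state.positions, rs)
            e_rg += e
            forces += f
        elif isinstance(rs, PositionRestraint):
            sel = np.asarray(rs.selection)
            d = state.positions[sel] - rs.reference_positions
            e_pos += 0.5 * rs.k_pr * float((d * d).sum())
            forces[sel] += -rs.k_pr * d
        else:
            raise TypeError(f"unknown restraint type {type(rs)!r}")
    terms = {
        "lj": e_lj, "wca": e_wca, "softcore": e_sc,
        "bond": e_bond, "angle": e_angle,
        "restraint_rg": e_rg, "restraint_pos": e_pos,
        "dudl": dudl, "virial": virial,
    }
    terms["potential"] = (e_lj + e_wca + e_sc + e_bond + e_angle
                          + e_rg + e_pos)
    return terms, forces


def virial_pressure(state: SystemState, ff: ForceFieldTable,
                    terms: dict | None = None,
                    temperature: float = 300.0,
                    truncation_correction: bool = True,
                    shell_width: float = 0.03) -> float:
    """Instantaneous pressure (bar) via the virial route,
    P = (N RT + W/3)/V with W = Σ F·r over pair and bond terms.

    Plain (unshifted) truncation makes the pair energy jump by −u(r_c)
    at the cutoff; the corresponding attractive impulsive virial
    u(r_c)·r_c·(dn_pairs/dr)|_{r_c} is estimated by counting pairs in a
    thin shell below the cutoff and is included by default — without it
    the pair-force virial overestimates the pressure of the truncated
    model by a few hundred bar at liquid density.
    """
    if terms is None:
        terms, _ = total_energy_forces(state, ff)
    volume = float(np.prod(state.box))
    w = terms["virial"]
    if truncation_correction and np.any(ff.mode == int(PairMode.LJ)):
        pos = state.wrapped_positions()
        d = pos[:, None, :] - pos[None, :, :]
        d -= state.box * np.rint(d / state.box)
        r = np.sqrt((d * d).sum(axis=2))
        iu = np.triu_indices(len(pos), k=1)
        rr = r[iu]
        si = state.species_index
        lj_pair = (ff.mode[si[iu[0]], si[iu[1]]] == int(PairMode.LJ))
        in_shell = lj_pair & (rr >= ff.cutoff - shell_width) & (rr < ff.cutoff)
        if in_shell.any():
            s_ij = ff.sigma[si[iu[0]][in_shell], si[iu[1]][in_shell]]
            e_ij = ff.epsilon[si[iu[0]][in_shell], si[iu[1]][in_shell]]
            sr6 = (s_ij / ff.cutoff) ** 6
            u_rc = 4.0 * e_ij * (sr6 * sr6 - sr6)
            w += float((u_rc * ff.cutoff).sum()) / shell_width
    p = (state.n_particles * R_GAS * temperature + w / 3.0) / volume
    return p / BAR_TO_KJ_PER_MOL_NM3


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def kinetic_energy(state: SystemState, masses: np.ndarray) -> float:
    m = masses[state.species_index]
    return 0.5 * float((m[:, None] * state.velocities ** 2).sum())


def draw_maxwell_velocities(state: SystemState, ff: ForceFieldTable,
                            temperature: float) -> None:
    """In-place Maxwell–Boltzmann velocity assignment at T."""
    m = ff.masses[state.species_index]
    sigma = np.sqrt(R_GAS * temperature / m)[:, None]
    state.velocities = sigma * state.rng.standard_normal(
        state.positions.shape)


def langevin_step(state: SystemState, ff: ForceFieldTable,
                  restraints: Sequence[object], spec: IntegratorSpec,
                  forces: np.ndarray | None = None
                  ) -> tuple[np.ndarray, dict]:
    """One BAOAB Langevin update; returns the new cached forces/terms.

    Deterministic given the state's RNG; the thermostat is local
    (momentum not conserved).  In the limit friction_time → ∞,
    T → 0 the map reduces to velocity Verlet.
    """
    m = ff.masses[state.species_index][:, None]
    dt = spec.dt
    if forces is None:
        _, forces = total_energy_forces(state, ff, restraints)
    # B
    state.velocities += 0.5 * dt * forces / m
    # A
    state.positions += 0.5 * dt * state.velocities
    # O
    c1 = np.exp(-dt / spec.friction_time)
    c2 = np.sqrt((1.0 - c1 * c1) * R_GAS * spec.temperature / m)
    state.velocities = (c1 * state.velocities
                        + c2 * state.rng.standard_normal(
                            state.velocities.shape))
    # A
    state.positions += 0.5 * dt * state.velocities
    max_disp = dt * np.abs(state.velocities).max()
    if not np.isfinite(max_disp) or max_disp > 10.0 * state.box.min():
        raise RuntimeError(
            f"integration blew up at step {state.step + 1}: max "
            f"displacement {max_disp:.3g} nm in one step")
    # B
    terms, forces = total_energy_forces(state, ff, restraints)
    state.velocities += 0.5 * dt * forces / m
    state.step += 1
    if not np.all(np.isfinite(state.positions)):
        raise RuntimeError(
            f"integration blew up at step {state.step}: non-finite "
            f"coordinates (max |v| = {np.abs(state.velocities).max():.3g})")
    return forces, terms


def _mc_volume_move(state: SystemState, ff: ForceFieldTable,
                    restraints: Sequence[object], spec: IntegratorSpec
                    ) -> bool:
    """Monte-Carlo volume move (isotropic ln-V step, molecular scaling).

    Molecules containing position-restrained particles are not scaled
    (their tethers are anchored in absolute coordinates), so the box
    relaxes around a frozen solute.
    """
    bar = spec.barostat
    p_target = bar.pressure_bar * BAR_TO_KJ_PER_MOL_NM3
    beta = 1.0 / (R_GAS * spec.temperature)
    terms0, _ = total_energy_forces(state, ff, restraints)
    v0 = float(np.prod(state.box))
    dlnv = (state.rng.random() * 2.0 - 1.0) * bar.max_dlnv
    s = np.exp(dlnv / 3.0)
    mol = state.topology.mol_id
    frozen_mols: set = set()
    for rs in restraints:
        if isinstance(rs, PositionRestraint):
            frozen_mols.update(np.unique(mol[np.asarray(rs.selection)]))
    scale_ids = [m for m in np.unique(mol) if m not in frozen_mols]
    n_mol = len(scale_ids)
    old_pos = state.positions.copy()
    old_box = state.box.copy()
    # scale molecular centres about the frozen solute (or box centre),
    # keeping internal geometry.  Coordinates are stored unwrapped; a
    # uniform dilation about a fixed point applied to the *raw*
    # coordinates scales periodic-image offsets consistently with the
    # box (nL -> n·sL), so raw offsets are the correct choice here —
    # taking the offset through the minimum image instead would leave
    # image offsets unscaled and kick every far-wandered molecule by
    # (s-1)·nL relative to its local environment.
    if frozen_mols:
        fsel = np.isin(mol, list(frozen_mols))
        origin = state.positions[fsel].mean(axis=0)
    else:
        origin = 0.5 * state.box
    for mid in scale_ids:
        idx = np.where(mol == mid)[0]
        cm = state.positions[idx].mean(axis=0)
        state.positions[idx] += (cm - origin) * (s - 1.0)
    state.box = state.box * s
    try:
        terms1, _ = total_energy_forces(state, ff, restraints)
    except (RuntimeError, ValueError):
        state.positions = old_pos
        state.box = old_box
        return False
    v1 = v0 * np.exp(dlnv)
    du = terms1["potential"] - terms0["potential"]
    arg = -beta * (du + p_target * (v1 - v0)) + (n_mol + 1) * dlnv
    if np.log(state.rng.random() + 1e-300) < arg:
        return True
    state.positions = old_pos
    state.box = old_box
    return False


@dataclass
class SegmentRecords:
    """Columnar observer records from :func:`run_segment`."""

    rows: list[dict] = field(default_factory=list)

    def column(self, key: str) -> np.ndarray:
        return np.array([row[key] for row in self.rows])


def run_segment(state: SystemState, ff: ForceFieldTable,
                restraints: Sequence[object], spec: IntegratorSpec,
                n_steps: int, observer_stride: int = 0,
                observers: Sequence[Callable] = ()) -> SegmentRecords:
    """Advance ``n_steps`` Langevin steps in place, sampling observers.

    Observers are callables ``(state, terms) -> dict`` merged into each
    record row at ``observer_stride`` intervals (records also carry the
    step index and the decomposed energies).
    """
    records = SegmentRecords()
    forces = None
    terms = None
    for k in range(n_steps):
        forces, terms = langevin_step(state, ff, restraints, spec, forces)
        if spec.barostat is not None and (k + 1) % spec.barostat.interval == 0:
            if _mc_volume_move(state, ff, restraints, spec):
                forces = None  # box changed; recompute next step
        if observer_stride and (k + 1) % observer_stride == 0:
            row = {"step": state.step, **{k2: terms[k2] for k2 in
                                          ("potential", "dudl")}}
            for obs in observers:
                row.update(obs(state, terms))
            records.rows.append(row)
    check_molecule_integrity(state)
    return records


def minimize(state: SystemState, ff: ForceFieldTable,
             restraints: Sequence[object] = (), max_steps: int = 500,
             tol: float = 10.0, initial_step: float = 0.01) -> float:
    """Steepest-descent energy minimisation in place.

    Moves along the normalised force direction with an adaptive step
    (grow 1.2× on downhill, halve on uphill) until ``max |F| < tol``
    (kJ/mol/nm) or ``max_steps``.  Returns the final potential energy;
    the final energy never exceeds the initial one.
    """
    terms, forces = total_energy_forces(state, ff, restraints)
    energy = terms["potential"]
    h = initial_step
    for _ in range(max_steps):
        fmax = np.abs(forces).max()
        if fmax < tol:
            break
        trial = state.positions + h * forces / fmax
        saved = state.positions
        state.positions = trial
        try:
            terms2, forces2 = total_energy_forces(state, ff, restraints)
            ok = terms2["potential"] <= energy
        except RuntimeError:
            ok = False
        if ok:
            energy = terms2["potential"]
            forces = forces2
            h = min(h * 1.2, 0.05)
        else:
            state.positions = saved
            h *= 0.5
            if h < 1e-8:
                break
    return float(energy)


# ---------------------------------------------------------------------------
# seeding helpers
# ---------------------------------------------------------------------------

def derive_seed(master_seed: int, *stream: int) -> int:
    """Deterministic child seed (< 2³¹) for a named RNG stream.

    Stream identifiers may be any integers; negatives are folded into
    the non-negative range SeedSequence requires (distinct from their
    positive counterparts).
    """
    ids = [int(master_seed) % (2 ** 31),
           *(int(s) % (2 ** 31) for s in stream)]
    ss = np.random.SeedSequence(ids)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
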