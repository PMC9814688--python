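"""Pair potentials, mixing rules and the interaction table.

Everything downstream (dynamics, umbrella sampling, thermodynamic
integration) reads interactions from a single :class:`ForceFieldTable`
built here.  Units are GROMACS-style throughout the package:
kJ·mol⁻¹ for energy, nm for length, ps for time, amu for mass, K for
temperature.  With these units 1 amu·nm²·ps⁻² = 1 kJ·mol⁻¹, so kinetic
energies and the gas constant R combine without conversion factors.

The model is a bead polymer (32 uncharged Lennard-Jones beads,
σ_p = 0.4 nm, ε_p = 1.0 kJ·mol⁻¹) in a binary solvent.  Unlike-pair
parameters follow Lorentz–Berthelot mixing; polymer–water and
polymer–alcohol well depths are then multiplied by dimensionless
scaling factors λ_pw and λ_pa (defaults 1.095 and 0.949) that tune the
solvent quality while leaving the diameters untouched.  For the cavity
(solvent-excluded-volume) calculations the polymer–solvent pairs are
switched to the purely repulsive Weeks–Chandler–Andersen (WCA) form,
optionally coupled through a Beutler-style soft core so the cavity can
be grown from nothing without an r → 0 singularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

# -- physical constants (kJ·mol⁻¹·K⁻¹; kJ·mol⁻¹·nm⁻³ per bar) ----------------
R_GAS = 0.0083145
BAR_TO_KJ_PER_MOL_NM3 = 0.060221
DEFAULT_CUTOFF = 1.4          # nm, plain truncation, no shift
TWO_SIXTH = 2.0 ** (1.0 / 6.0)

# Default bead-polymer parameters.
SIGMA_P = 0.4                 # nm
EPSILON_P = 1.0               # kJ/mol
LAMBDA_PW_DEFAULT = 1.095
LAMBDA_PA_DEFAULT = 0.949

# Bonded defaults.  The published bead-polymer source does not print its
# bond/angle constants, so these are package defaults chosen to give a
# stiff tangent-bead chain; they are configurable and documented as
# placeholders, not literature values.
DEFAULT_BOND_R0 = 0.4         # nm
DEFAULT_BOND_K = 30000.0      # kJ/mol/nm^2
DEFAULT_ANGLE_THETA0 = np.pi  # rad (180 deg)
DEFAULT_ANGLE_K = 2.0         # kJ/mol/rad^2 (weakly semiflexible)


class PairMode(IntEnum):
    """Which energy function is legal for a pair of species."""

    LJ = 0
    WCA = 1
    SOFTCORE_WCA = 2
    EXCLUDED = 3


@dataclass(frozen=True)
class Species:
    """One particle type.

    Parameters
    ----------
    name : str
    sigma : float
        LJ diameter (nm), > 0.
    epsilon : float
        LJ well depth (kJ/mol), >= 0.
    mass : float
        Particle mass (amu), > 0.
    role : {"polymer", "water", "alcohol"}
        Determines which λ-scaling and mode switches apply.
    """

    name: str
    sigma: float
    epsilon: float
    mass: float
    role: str

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")
        if self.role not in ("polymer", "water", "alcohol"):
            raise ValueError(f"unknown species role {self.role!r}")


@dataclass(frozen=True)
class PairParams:
    """Mixed parameters for one species pair."""

    sigma_ij: float
    epsilon_ij: float
    mode: PairMode = PairMode.LJ

    def __post_init__(self) -> None:
        if self.sigma_ij <= 0:
            raise ValueError("sigma_ij must be > 0")
        if self.epsilon_ij < 0:
            raise ValueError("epsilon_ij must be >= 0")


@dataclass(frozen=True)
class LambdaScaling:
    """Multiplicative scaling of polymer–solvent well depths."""

    lambda_pw: float = LAMBDA_PW_DEFAULT
    lambda_pa: float = LAMBDA_PA_DEFAULT

    def __post_init__(self) -> None:
        if self.lambda_pw <= 0 or self.lambda_pa <= 0:
            raise ValueError("lambda scalings must be > 0")


@dataclass(frozen=True)
class SoftCoreParams:
    """Beutler-form soft-core parameters (α, p, σ_sc)."""

    alpha: float = 0.5
    p: int = 1
    sigma_sc: float = 0.3  # nm

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.sigma_sc <= 0:
            raise ValueError("sigma_sc must be > 0")


# ---------------------------------------------------------------------------
# scalar pair potentials
# ---------------------------------------------------------------------------

def lj_energy_force(r: float, pp: PairParams,
                    cutoff: float = DEFAULT_CUTOFF) -> tuple[float, float]:
    """Full Lennard-Jones energy and radial force magnitude.

    Returns ``(U, F)`` with ``U = 4ε[(σ/r)^12 − (σ/r)^6]`` and
    ``F = −dU/dr``; both are zero beyond ``cutoff`` (plain truncation,
    no shift).
    """
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    if pp.mode != PairMode.LJ:
        raise ValueError(f"pair mode {pp.mode!r} does not define a full-LJ energy")
    if r > cutoff:
        return 0.0, 0.0
    sr6 = (pp.sigma_ij / r) ** 6
    u = 4.0 * pp.epsilon_ij * (sr6 * sr6 - sr6)
    f = 24.0 * pp.epsilon_ij * (2.0 * sr6 * sr6 - sr6) / r
    return u, f


def wca_energy_force(r: float, pp: PairParams) -> tuple[float, float]:
    """Weeks–Chandler–Andersen repulsive reference: LJ + ε for
    r ≤ 2^{1/6}σ, exactly zero beyond.  Continuous at the split point,
    non-negative everywhere."""
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    rmin = TWO_SIXTH * pp.sigma_ij
    if r > rmin:
        return 0.0, 0.0
    sr6 = (pp.sigma_ij / r) ** 6
    u = 4.0 * pp.epsilon_ij * (sr6 * sr6 - sr6) + pp.epsilon_ij
    f = 24.0 * pp.epsilon_ij * (2.0 * sr6 * sr6 - sr6) / r
    return u, f


def softcore_energy_dudl(r: float, pp: PairParams, lam: float,
                         sc: SoftCoreParams) -> tuple[float, float]:
    """Soft-core-coupled WCA pair energy and ∂U/∂λ.

    Beutler form with r⁶ mixing::

        r_sc = (α σ_sc⁶ (1−λ)^p + r⁶)^{1/6}
        V(r; λ) = λ · V_WCA(r_sc)

    At λ = 1 this reduces exactly to the plain WCA pair energy; at λ = 0
    the energy vanishes while ∂U/∂λ stays finite for every r ≥ 0,
    including full overlap (r = 0), which is the point of the soft core.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if r < 0:
        raise ValueError("r must be >= 0")
    shift = sc.alpha * sc.sigma_sc ** 6 * (1.0 - lam) ** sc.p
    r6 = r ** 6
    rsc = (shift + r6) ** (1.0 / 6.0)
    if rsc == 0.0:
        # only reachable for lam == 1 and r == 0 (hard overlap of the
        # fully coupled WCA pair) — genuinely singular.
        raise ValueError("soft-core separation is zero at full coupling")
    u_wca, f_wca = wca_energy_force(rsc, pp)   # f_wca = -dV_WCA/dr at rsc
    energy = lam * u_wca
    # dU/dlam = V_WCA(rsc) + lam * V'_WCA(rsc) * drsc/dlam
    if sc.p == 1:
        dshift = -sc.alpha * sc.sigma_sc ** 6
    else:
        dshift = -sc.alpha * sc.sigma_sc ** 6 * sc.p * (1.0 - lam) ** (sc.p - 1)
    drsc_dlam = dshift / (6.0 * rsc ** 5)
    dudl = u_wca + lam * (-f_wca) * drsc_dlam
    return energy, dudl


def softcore_force(r: float, pp: PairParams, lam: float,
                   sc: SoftCoreParams) -> float:
    """Radial force magnitude −dV_sc/dr of the soft-core WCA pair."""
    if r <= 0:
        return 0.0  # gradient vanishes at full overlap (soft core is flat)
    shift = sc.alpha * sc.sigma_sc ** 6 * (1.0 - lam) ** sc.p
    rsc = (shift + r ** 6) ** (1.0 / 6.0)
    _, f_wca = wca_energy_force(rsc, pp)
    # dV/dr = lam * V'_WCA(rsc) * drsc/dr, drsc/dr = r^5 / rsc^5
    return lam * f_wca * (r ** 5 / rsc ** 5)


# ---------------------------------------------------------------------------
# force-field table
# ---------------------------------------------------------------------------

@dataclass
class ForceFieldTable:
    """Mixed per-pair parameters plus bonded and soft-core settings.

    Attributes
    ----------
    species : list of Species
    sigma, epsilon : (S, S) arrays of mixed pair parameters.
    mode : (S, S) int array of :class:`PairMode` codes.
    cutoff : LJ truncation radius (nm).
    softcore : SoftCoreParams used by SOFTCORE_WCA pairs.
    lam : coupling parameter applied to SOFTCORE_WCA pairs.
    sc_pair_sigma : use each pair's own σ_ij as the soft-core σ instead
        of the global ``softcore.sigma_sc``.  The free-energy endpoints
        are independent of the soft-core parameters (they only shape
        the integration path), so this is a pure variance-reduction
        option for campaigns whose pair diameters differ from the
        default soft-core σ.
    bond_k, bond_r0, angle_k, angle_theta0 : harmonic bonded constants.
    """

    species: list[Species]
    sigma: np.ndarray
    epsilon: np.ndarray
    mode: np.ndarray
    cutoff: float = DEFAULT_CUTOFF
    softcore: SoftCoreParams = field(default_factory=SoftCoreParams)
    lam: float = 1.0
    sc_pair_sigma: bool = False
    bond_k: float = DEFAULT_BOND_K
    bond_r0: float = DEFAULT_BOND_R0
    angle_k: float = DEFAULT_ANGLE_K
    angle_theta0: float = DEFAULT_ANGLE_THETA0

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.species])

    def pair(self, i: int, j: int) -> PairParams:
        return PairParams(self.sigma[i, j], self.epsilon[i, j],
                          PairMode(int(self.mode[i, j])))

    def with_lambda(self, lam: float) -> "ForceFieldTable":
        """Copy of the table at a different soft-core coupling."""
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        return ForceFieldTable(self.species, self.sigma, self.epsilon,
                               self.mode, self.cutoff, self.softcore, lam,
                               self.sc_pair_sigma,
                               self.bond_k, self.bond_r0,
                               self.angle_k, self.angle_theta0)


def build_forcefield(species: Sequence[Species],
                     scaling: LambdaScaling | None = None,
                     wca_polymer_solvent: bool = False,
                     cutoff: float = DEFAULT_CUTOFF,
                     softcore: SoftCoreParams | None = None,
                     softcore_polymer_solvent: bool = False,
                     **bonded) -> ForceFieldTable:
    """Build the mixed interaction table.

    Lorentz–Berthelot mixing (σ_ij = (σ_i+σ_j)/2, ε_ij = √(ε_i ε_j)),
    then polymer–water ε multiplied by λ_pw and polymer–alcohol ε by
    λ_pa, diameters unchanged.  With ``wca_polymer_solvent`` the
    polymer–solvent pair modes become WCA (λ-scaling is then irrelevant
    to those pairs); ``softcore_polymer_solvent`` additionally marks
    them for soft-core λ-coupling, as used in the cavity TI.
    """
    scaling = scaling or LambdaScaling()
    softcore = softcore or SoftCoreParams()
    n = len(species)
    roles = [s.role for s in species]
    sig = np.zeros((n, n))
    eps = np.zeros((n, n))
    mode = np.full((n, n), int(PairMode.LJ), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            sig[i, j] = 0.5 * (species[i].sigma + species[j].sigma)
            eps[i, j] = np.sqrt(species[i].epsilon * species[j].epsilon)
            pair_roles = {roles[i], roles[j]}
            if pair_roles == {"polymer", "water"}:
                eps[i, j] *= scaling.lambda_pw
            elif pair_roles == {"polymer", "alcohol"}:
                eps[i, j] *= scaling.lambda_pa
            if "polymer" in pair_roles and pair_roles != {"polymer"}:
                if softcore_polymer_solvent:
                    mode[i, j] = int(PairMode.SOFTCORE_WCA)
                elif wca_polymer_solvent:
                    mode[i, j] = int(PairMode.WCA)
    return ForceFieldTable(list(species), sig, eps, mode, cutoff=cutoff,
                           softcore=softcore, **bonded)


def default_polymer_species(name: str = "P") -> Species:
    """The 32-bead-polymer bead type (σ = 0.4 nm, ε = 1.0 kJ/mol)."""
    return Species(name, SIGMA_P, EPSILON_P, mass=40.0, role="polymer")
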