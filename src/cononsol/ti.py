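"""Cavity (solvent-excluded-volume) free energies by thermodynamic
integration.

The reversible work of creating a repulsive polymer-shaped cavity in
the binary solvent, ΔG_Excl-Vol, is computed for *fixed* coil and
globule conformations: the chain is frozen by stiff per-particle
position restraints (k = 10⁵ kJ·mol⁻¹·nm⁻²), its purely repulsive
(WCA) interactions with every solvent site are switched on through a
Beutler soft core (α = 0.5, p = 1, σ_sc = 0.3 nm), and ⟨∂U/∂λ⟩ is
integrated over a λ-grid (default 21 points, spacing 0.05) by the
trapezoidal rule.  λ = 0 is the cavity-free binary solvent (the
restrained chain is a ghost); λ = 1 is the fully coupled cavity.
Intramolecular polymer terms are retained at every λ — they are
λ-independent and cancel in all ΔG differences.

The coil–globule difference ΔΔG^C→G_Excl-Vol = ΔG^G − ΔG^C is the
excluded-volume contribution to the collapse free energy; it is
negative whenever the compact globule imposes a smaller interfacial
cost than the extended coil.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .forcefield import ForceFieldTable
from .mdengine import (IntegratorSpec, PositionRestraint, SystemState,
                       derive_seed, draw_maxwell_velocities, minimize,
                       run_segment)
from .synth import ReducedSolventSpec, build_mixture


@dataclass(frozen=True)
class LambdaSchedule:
    values: tuple = tuple(np.round(np.linspace(0.0, 1.0, 21), 10))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) < 2 or v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("λ schedule must start at 0 and end at 1")
        if np.any(np.diff(v) <= 0):
            raise ValueError("λ schedule must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class TIResult:
    lambdas: np.ndarray
    dudl_mean: np.ndarray          # kJ/mol
    dudl_stderr: np.ndarray
    dg: float                      # kJ/mol
    dg_stderr: float
    conformation: str = ""         # {"coil", "globule", ...}
    x_alcohol: float = float("nan")
    shell_water: float = float("nan")    # mean first-shell counts at λ=1
    shell_alcohol: float = float("nan")
    gamma: float = float("nan")          # preferential binding at λ=1


@dataclass(frozen=True)
class TIProtocol:
    """Desk-scale per-λ sampling protocol (all durations configurable).

    Each run relaxes its own volume by ``n_npt_steps`` of MC-barostat
    (NPT) dynamics at the fully coupled state and ``pressure_bar``,
    started from a dense lattice so the solvent wets the cavity; the
    box is then fixed at the NPT-*average* volume for the descending
    NVT λ-sweep (the instantaneous box carries ~0.3 % volume noise
    that the density-sensitive cavity work would amplify).  The NPT
    stage doubles as adsorption equilibration of the cosolvent shell;
    ``n_equil_first_steps`` is the extra NVT equilibration of the
    first sweep leg after the box rescale.  ``sc_pair_sigma`` makes
    the soft core use each pair's own σ_ij, which flattens the low-λ
    integrand for the bulky reduced-model pairs; it changes the
    integration path only, never the endpoints.
    """

    schedule: LambdaSchedule = field(default_factory=LambdaSchedule)
    n_equil_steps: int = 1000
    n_prod_steps: int = 3000
    sample_stride: int = 10
    n_blocks: int = 5
    k_pr: float = 1.0e5            # kJ/mol/nm^2 position restraints
    integrator: IntegratorSpec = field(default_factory=IntegratorSpec)
    minimize_steps: int = 200
    n_equil_first_steps: int = 3000
    n_npt_steps: int = 8000
    pressure_bar: float = 1000.0
    npt_interval: int = 10
    npt_max_dlnv: float = 0.01
    sc_pair_sigma: bool = True
    # extra relaxation where the cavity refills during the descending
    # sweep: for λ below the threshold, equilibration and production
    # are stretched by the given factors (solvent penetration into the
    # weakly coupled core is diffusive and slow, unlike expulsion)
    low_lambda_threshold: float = 0.35
    low_lambda_equil_factor: int = 2
    low_lambda_prod_factor: float = 1.5


def refined_low_lambda_schedule() -> LambdaSchedule:
    """11-point schedule concentrated where the integrand is steep and
    slow (the low-λ cavity-refilling regime)."""
    return LambdaSchedule((0.0, 0.03, 0.06, 0.1, 0.15, 0.2, 0.3,
                           0.45, 0.6, 0.8, 1.0))


def prepare_cavity_system(conformer: SystemState,
                          solvent: ReducedSolventSpec,
                          x_alcohol: float, n_solvent: int,
                          box_edge: float, seed: int,
                          k_pr: float = 1.0e5,
                          protocol: TIProtocol | None = None,
                          ) -> tuple[SystemState, ForceFieldTable,
                                     PositionRestraint, dict]:
    """Solvate a frozen conformer for cavity TI.

    The polymer snapshot is centred in the box, solvent is placed on a
    shuffled lattice at the requested composition (liquid densities jam
    random insertion), polymer–solvent pairs are set to soft-core WCA,
    each polymer bead is tethered to its reference position, and the
    system is energy-minimised at full coupling.  When a protocol is
    given, the box is then relaxed by the MC-barostat NPT stage at
    ``protocol.pressure_bar`` and finally *fixed at the NPT-average
    volume* (solvent molecule centres dilated about the solute, raw
    offsets, so periodic-image offsets scale with the box).  The dense
    lattice start matters: it
    selects the wetted branch of the cavity — from dilute starts the
    purely repulsive surface can nucleate a vapour film instead.
    """
    state, ff, index = build_mixture(
        solvent, x_alcohol, n_solvent, box_edge, seed,
        polymer_state=conformer, softcore_polymer_solvent=True,
        placement="lattice")
    if protocol is not None:
        ff.sc_pair_sigma = protocol.sc_pair_sigma
    n_p = len(conformer.positions)
    sel = np.arange(n_p)
    restraint = PositionRestraint(k_pr=k_pr,
                                  reference_positions=state.positions[sel].copy(),
                                  selection=sel)
    ff1 = ff.with_lambda(1.0)
    minimize(state, ff1, [restraint], max_steps=300, tol=200.0)
    if protocol is not None and protocol.n_npt_steps > 0:
        from .mdengine import MCBarostat
        npt = replace(protocol.integrator,
                      barostat=MCBarostat(protocol.pressure_bar,
                                          protocol.npt_interval,
                                          protocol.npt_max_dlnv))
        draw_maxwell_velocities(state, ff1,
                                protocol.integrator.temperature)
        half = protocol.n_npt_steps // 2
        run_segment(state, ff1, [restraint], npt, half)
        rec = run_segment(state, ff1, [restraint], npt,
                          protocol.n_npt_steps - half,
                          observer_stride=protocol.npt_interval,
                          observers=[lambda s, t: {"L": float(s.box[0])}])
        l_target = float(np.mean(rec.column("L")))
        s = l_target / float(state.box[0])
        mol = state.topology.mol_id
        origin = state.positions[sel].mean(axis=0)
        for mid in np.unique(mol):
            if np.any(np.isin(np.where(mol == mid)[0], sel)):
                continue
            i = np.where(mol == mid)[0]
            cm = state.positions[i].mean(axis=0)
            # raw offsets: dilation about a fixed point scales image
            # offsets consistently with the box (see _mc_volume_move)
            state.positions[i] += (cm - origin) * (s - 1.0)
        state.box = state.box * s
    return state, ff, restraint, index


def sample_dudl(state: SystemState, ff: ForceFieldTable,
                restraints: Sequence[object], lam: float,
                protocol: TIProtocol, seed: int,
                extra_observers: Sequence = ()) -> tuple[float, float,
                                                         "object"]:
    """⟨∂U/∂λ⟩ at one λ with block-averaged standard error.

    Starts from a copy of ``state`` with a λ-specific RNG stream and
    fresh Maxwell–Boltzmann velocities, minimises, equilibrates
    (discarded), then accumulates the soft-core ∂U/∂λ every
    ``sample_stride`` steps.  Returns (mean, stderr, records).
    """
    ffl = ff.with_lambda(lam)
    s = state.replace_rng(seed)
    draw_maxwell_velocities(s, ffl, protocol.integrator.temperature)
    minimize(s, ffl, restraints, max_steps=protocol.minimize_steps,
             tol=500.0)
    run_segment(s, ffl, restraints, protocol.integrator,
                protocol.n_equil_steps)
    rec = run_segment(s, ffl, restraints, protocol.integrator,
                      protocol.n_prod_steps,
                      observer_stride=protocol.sample_stride,
                      observers=list(extra_observers))
    series = rec.column("dudl")
    blocks = np.array_split(series, protocol.n_blocks)
    bmeans = np.array([b.mean() for b in blocks])
    mean = float(series.mean())
    stderr = float(bmeans.std(ddof=1) / np.sqrt(len(bmeans)))
    return mean, stderr, rec


def sweep_dudl(state: SystemState, ff: ForceFieldTable,
               restraints: Sequence[object], protocol: TIProtocol,
               seed: int, frames_at: float | None = None,
               frame_slice: slice = slice(None)
               ) -> tuple[np.ndarray, np.ndarray, list]:
    """Descending carried-state ⟨∂U/∂λ⟩ sweep over the schedule.

    The generic single-system analogue of the campaign sweep: each λ
    inherits the previous λ's configuration (fresh velocities, per-λ
    RNG streams), which suppresses the trapped-particle hysteresis of
    independent per-λ starts.  Optionally collects position frames at
    one λ (``frames_at``), e.g. λ = 0 for a Widom reference ensemble.
    Returns (means, stderrs, frames).
    """
    lam_values = protocol.schedule.array
    means = np.zeros(len(lam_values))
    errs = np.zeros(len(lam_values))
    frames: list = []
    current = state
    first = True
    for k, lam in reversed(list(enumerate(lam_values))):
        ffl = ff.with_lambda(lam)
        current = current.replace_rng(derive_seed(seed, 10, k))
        draw_maxwell_velocities(current, ffl,
                                protocol.integrator.temperature)
        n_eq = protocol.n_equil_first_steps if first \
            else protocol.n_equil_steps
        first = False
        run_segment(current, ffl, restraints, protocol.integrator, n_eq)
        obs = []
        if frames_at is not None and lam == frames_at:
            obs = [lambda s, t: {"positions": s.positions.copy()}]
        rec = run_segment(current, ffl, restraints, protocol.integrator,
                          protocol.n_prod_steps,
                          observer_stride=protocol.sample_stride,
                          observers=obs)
        series = rec.column("dudl")
        blocks = np.array_split(series, protocol.n_blocks)
        bmeans = np.array([b.mean() for b in blocks])
        means[k] = float(series.mean())
        errs[k] = float(bmeans.std(ddof=1) / np.sqrt(len(bmeans)))
        if obs:
            frames = [r["positions"][frame_slice] for r in rec.rows]
    return means, errs, frames


def integrate_ti(schedule: LambdaSchedule, dudl_mean: np.ndarray,
                 dudl_stderr: np.ndarray | None = None,
                 method: str = "trapezoid") -> tuple[float, float]:
    """Quadrature of ⟨∂U/∂λ⟩ over λ.

    Trapezoid by default (matching the evenly spaced 21-point
    schedule); Simpson optional.  The error is propagated as the square
    root of the quadrature-weighted sum of per-λ variances, treating
    the λ-points as independent.
    """
    lam = schedule.array
    y = np.asarray(dudl_mean, dtype=float)
    if len(y) != len(lam):
        raise ValueError("dudl series length does not match schedule")
    if method == "trapezoid":
        dg = float(np.trapezoid(y, lam))
        wts = np.zeros_like(lam)
        wts[0] = 0.5 * (lam[1] - lam[0])
        wts[-1] = 0.5 * (lam[-1] - lam[-2])
        wts[1:-1] = 0.5 * (lam[2:] - lam[:-2])
    elif method == "simpson":
        from scipy.integrate import simpson
        dg = float(simpson(y, x=lam))
        # conservative: fall back to trapezoid weights for the error
        wts = np.gradient(lam)
    else:
        raise ValueError(f"unknown quadrature {method!r}")
    if dudl_stderr is None:
        err = 0.0
    else:
        err = float(np.sqrt(np.sum((wts * np.asarray(dudl_stderr)) ** 2)))
    return dg, err


def excl_vol_difference(coil: TIResult, globule: TIResult
                        ) -> tuple[float, float]:
    """ΔΔG^C→G_Excl-Vol = ΔG^G − ΔG^C with combined standard error.

    A compact globule exposes less surface than the coil, so the
    difference is expected negative; a positive value triggers a
    warning, not an error.
    """
    ddg = globule.dg - coil.dg
    err = float(np.hypot(coil.dg_stderr, globule.dg_stderr))
    if ddg > 0:
        warnings.warn(
            f"ΔΔG_Excl-Vol = {ddg:.2f} kJ/mol > 0: globule cavity "
            "costs more than coil, violating the expected sign",
            RuntimeWarning)
    return float(ddg), err


def run_cavity_ti(conformer: SystemState, solvent: ReducedSolventSpec,
                  x_alcohol: float, n_solvent: int, box_edge: float,
                  protocol: TIProtocol, seed: int,
                  conformation_tag: str = "",
                  shell_cutoff: float = 0.65,
                  adsorption_extra: int = 3) -> TIResult:
    """Full TI for one conformation at one composition.

    The λ-points are visited as a *sweep* from the NPT-equilibrated
    fully coupled state downward: each λ inherits the previous λ's
    configuration (with fresh Maxwell–Boltzmann velocities and its own
    RNG stream), so the solvent flows back into the shrinking cavity
    gradually — independent per-λ starts leave particles trapped in
    the core whose relaxation both biases and inflates the variance of
    ⟨∂U/∂λ⟩.  At λ = 1 the production run is extended
    ``adsorption_extra``-fold and additionally samples first-shell
    solvent/cosolvent counts and the preferential-binding coefficient
    Γ, which the adsorption analysis consumes.
    """
    from .solvation import first_shell_counts, preferential_binding_frames

    state, ff, restraint, index = prepare_cavity_system(
        conformer, solvent, x_alcohol, n_solvent, box_edge,
        derive_seed(seed, 3), k_pr=protocol.k_pr, protocol=protocol)
    n_p = len(conformer.positions)
    lam_values = protocol.schedule.array
    means = np.zeros(len(lam_values))
    errs = np.zeros(len(lam_values))
    shell_w = shell_a = gamma = float("nan")
    current = state
    first = True
    for k, lam in reversed(list(enumerate(lam_values))):
        ffl = ff.with_lambda(lam)
        current = current.replace_rng(derive_seed(seed, 10, k))
        draw_maxwell_velocities(current, ffl,
                                protocol.integrator.temperature)
        n_eq = protocol.n_equil_first_steps if first \
            else protocol.n_equil_steps
        first = False
        n_prod = protocol.n_prod_steps
        if lam < protocol.low_lambda_threshold:
            n_eq = protocol.n_equil_steps * protocol.low_lambda_equil_factor
            n_prod = int(protocol.n_prod_steps
                         * protocol.low_lambda_prod_factor)
        run_segment(current, ffl, [restraint], protocol.integrator,
                    n_eq)
        obs = []
        if lam == 1.0:
            n_prod = protocol.n_prod_steps * adsorption_extra
            obs = [lambda s, t: {"positions": s.positions.copy()}]
        rec = run_segment(current, ffl, [restraint], protocol.integrator,
                          n_prod, observer_stride=protocol.sample_stride,
                          observers=obs)
        series = rec.column("dudl")
        blocks = np.array_split(series, protocol.n_blocks)
        bmeans = np.array([b.mean() for b in blocks])
        means[k] = float(series.mean())
        errs[k] = float(bmeans.std(ddof=1) / np.sqrt(len(bmeans)))
        if lam == 1.0 and rec.rows:
            frames = [row["positions"] for row in rec.rows]
            counts = [first_shell_counts(pos, current.box,
                                         current.species_index,
                                         current.topology.mol_id,
                                         np.arange(n_p), index,
                                         shell_cutoff)
                      for pos in frames]
            shell_w = float(np.mean([c[0] for c in counts]))
            shell_a = float(np.mean([c[1] for c in counts]))
            gamma, _ = preferential_binding_frames(
                frames, current.box, current.species_index,
                current.topology.mol_id, np.arange(n_p), index,
                shell_cutoff)
    dg, dg_err = integrate_ti(protocol.schedule, means, errs)
    return TIResult(lam_values, means, errs, dg, dg_err,
                    conformation=conformation_tag, x_alcohol=x_alcohol,
                    shell_water=shell_w, shell_alcohol=shell_a,
                    gamma=gamma)


def ti_campaign(coil: SystemState, globule: SystemState,
                solvent: ReducedSolventSpec,
                x_grid: Sequence[float], n_solvent: int, box_edge: float,
                protocol: TIProtocol, seed: int
                ) -> tuple[pd.DataFrame, dict[tuple[str, float], TIResult]]:
    """Cavity TI over a composition grid for both conformations.

    Returns a tidy table with one row per composition —
    ΔG^C_Excl-Vol, ΔG^G_Excl-Vol, ΔΔG^C→G and errors, first-shell
    adsorption numbers — plus the per-run :class:`TIResult` records.
    Seeds are independent per (conformation, composition).

    ``n_solvent`` is the pure-water reference count; compositions run
    at matched packing fraction (``matched_solvent_count``).  Each run
    finds its own isobaric volume through the NPT stage of
    :func:`prepare_cavity_system` (dense start at ``box_edge``,
    NPT-averaged, then fixed for the NVT sweep), so coil and globule
    are compared at the campaign pressure with each conformation at
    its own equilibrium (wetted-branch) volume.
    """
    from .synth import matched_solvent_count

    results: dict[tuple[str, float], TIResult] = {}
    rows = []
    for ix, x in enumerate(x_grid):
        pair = {}
        n_x = matched_solvent_count(solvent, x, n_solvent)
        for tag, conf in (("coil", coil), ("globule", globule)):
            res = run_cavity_ti(conf, solvent, x, n_x, box_edge,
                                protocol,
                                derive_seed(seed, 1000 + ix,
                                            0 if tag == "coil" else 1),
                                conformation_tag=tag)
            results[(tag, x)] = res
            pair[tag] = res
        ddg, ddg_err = excl_vol_difference(pair["coil"], pair["globule"])
        rows.append({
            "x_alcohol": x,
            "dg_coil": pair["coil"].dg,
            "dg_coil_err": pair["coil"].dg_stderr,
            "dg_globule": pair["globule"].dg,
            "dg_globule_err": pair["globule"].dg_stderr,
            "ddg": ddg, "ddg_err": ddg_err,
            "shell_alcohol_coil": pair["coil"].shell_alcohol,
            "shell_alcohol_globule": pair["globule"].shell_alcohol,
            "gamma_coil": pair["coil"].gamma,
            "gamma_globule": pair["globule"].gamma,
        })
    table = pd.DataFrame(rows)
    return table, results


def campaign_minimum(table: pd.DataFrame) -> tuple[float, float]:
    """(X at the ΔΔG minimum, ΔΔG there) from a campaign table."""
    i = int(table["ddg"].idxmin())
    return float(table["x_alcohol"][i]), float(table["ddg"][i])
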