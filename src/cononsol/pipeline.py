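"""End-to-end drivers: the cononsolvency composition scan.

Glues the synthetic reduced-solvent model, conformer generation,
cavity TI and the adsorption analysis into the Fig-style outputs:
ΔG_Excl-Vol(X) per conformation, ΔΔG^C→G(X) with its interior minimum
X_c,min, first-shell adsorption numbers, and the saturation
concentration of the globule shell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CampaignConfig
from .mdengine import derive_seed, draw_maxwell_velocities, run_segment
from .solvation import (AdsorptionProfile, preferential_binding_frames,
                        saturation_concentration)
from .synth import (ReducedSolventSpec, ethanol_like_spec,
                    make_conformers, matched_solvent_count)
from .ti import (TIProtocol, campaign_minimum, prepare_cavity_system,
                 ti_campaign)


def solvent_spec_from_config(cfg: CampaignConfig) -> ReducedSolventSpec:
    if cfg.system.alcohol_model == "ethanol":
        return ethanol_like_spec(cross_eps_scale=cfg.system.cross_eps_scale)
    return ReducedSolventSpec(cross_eps_scale=cfg.system.cross_eps_scale)


def adsorption_run(conformer, solvent: ReducedSolventSpec, x_alcohol: float,
                   n_solvent: int, box_edge: float, protocol: TIProtocol,
                   seed: int, n_equil: int = 4000, n_prod: int = 30000,
                   stride: int = 100, shell_cutoff: float = 0.65,
                   n_blocks: int = 5) -> tuple[float, float]:
    """Preferential-binding coefficient Γ of the fully coupled (WCA)
    frozen conformer from a dedicated long run.

    Shell↔bulk exchange of the adsorbed cosolvent is slow (tens of ps),
    so Γ needs far longer sampling than ⟨∂U/∂λ⟩; the TI sweep's λ = 1
    leg gives shell occupancies but not a converged Γ.  Returns
    (Γ, block standard error).
    """
    state, ff, restraint, index = prepare_cavity_system(
        conformer, solvent, x_alcohol, n_solvent, box_edge,
        derive_seed(seed, 3), k_pr=protocol.k_pr, protocol=protocol)
    ff1 = ff.with_lambda(1.0)
    state = state.replace_rng(derive_seed(seed, 4))
    draw_maxwell_velocities(state, ff1, protocol.integrator.temperature)
    run_segment(state, ff1, [restraint], protocol.integrator, n_equil)
    rec = run_segment(state, ff1, [restraint], protocol.integrator,
                      n_prod, observer_stride=stride,
                      observers=[lambda s, t: {
                          "pos": s.positions.copy()}])
    frames = [r["pos"] for r in rec.rows]
    sel = np.arange(len(conformer.positions))
    gamma, _ = preferential_binding_frames(
        frames, state.box, state.species_index, state.topology.mol_id,
        sel, index, shell_cutoff)
    nb = max(1, len(frames) // n_blocks)
    blocks = [preferential_binding_frames(
        frames[i * nb:(i + 1) * nb], state.box, state.species_index,
        state.topology.mol_id, sel, index, shell_cutoff)[0]
        for i in range(n_blocks)]
    stderr = float(np.std(blocks, ddof=1) / np.sqrt(n_blocks))
    return float(gamma), stderr


def adsorption_campaign(coil, globule, solvent: ReducedSolventSpec,
                        x_values, n_solvent: int, box_edge: float,
                        protocol: TIProtocol, seed: int, **kw
                        ) -> pd.DataFrame:
    """Γ for both conformations over low compositions (tidy table)."""
    rows = []
    for ix, x in enumerate(x_values):
        n_x = matched_solvent_count(solvent, x, n_solvent)
        row = {"x_alcohol": x}
        for tag, conf in (("coil", coil), ("globule", globule)):
            g, ge = adsorption_run(
                conf, solvent, x, n_x, box_edge, protocol,
                derive_seed(seed, 2000 + ix, 0 if tag == "coil" else 1),
                **kw)
            row[f"gamma_{tag}"] = g
            row[f"gamma_{tag}_err"] = ge
        rows.append(row)
    return pd.DataFrame(rows)


def scan_cononsolvency(cfg: CampaignConfig, seed: int | None = None
                       ) -> dict:
    """Run the full composition scan at the configured desk scale.

    Returns a dict with the campaign ``table`` (one row per X), the
    per-run TI ``results``, the ΔΔG minimum location ``x_c_min`` and
    the globule-shell ``saturation`` analysis.
    """
    seed = cfg.master_seed if seed is None else seed
    solvent = solvent_spec_from_config(cfg)
    coil = make_conformers(cfg.system.n_beads, "coil",
                           derive_seed(seed, 11),
                           temperature=cfg.temperature_K)
    globule = make_conformers(cfg.system.n_beads, "globule",
                              derive_seed(seed, 12),
                              temperature=cfg.temperature_K)
    protocol = cfg.ti_protocol()
    table, results = ti_campaign(
        coil, globule, solvent, cfg.system.composition_grid,
        cfg.system.n_solvent, cfg.system.box_edge_nm, protocol,
        derive_seed(seed, 13))
    x_min, ddg_min = campaign_minimum(table)
    x_low = [x for x in cfg.system.composition_grid if x > 0][:2]
    adsorption = adsorption_campaign(
        coil, globule, solvent, x_low, cfg.system.n_solvent,
        cfg.system.box_edge_nm, protocol, derive_seed(seed, 14),
        n_equil=5 * cfg.ti.n_equil_steps,
        n_prod=12 * cfg.ti.n_prod_steps,
        shell_cutoff=cfg.analysis.shell_cutoff_nm)
    nonzero = table[table["x_alcohol"] > 0]
    sat = None
    diag: dict = {}
    if len(nonzero) >= 3:
        profile = AdsorptionProfile(
            x_alcohol=table["x_alcohol"].to_numpy(),
            shell_alcohol=table["shell_alcohol_globule"].to_numpy(),
            shell_water=np.zeros(len(table)),
            conformation="globule")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sat, diag = saturation_concentration(profile)
    return {"table": table, "results": results,
            "x_c_min": x_min, "ddg_min": ddg_min,
            "adsorption": adsorption,
            "saturation_x": sat, "saturation_diag": diag,
            "conformers": {"coil": coil, "globule": globule}}


def preset_config(name: str) -> CampaignConfig:
    """Named desk-scale presets.

    ``tiny``  — the 32-bead chain in ~450 solvent molecules, 11-point λ
    grid, short per-λ runs: the smallest preset on which the mechanism
    properties are resolved.
    ``smoke`` — a 12-bead chain in 60 solvent molecules: seconds-scale
    end-to-end exercise of every stage, for plumbing checks only.
    """
    cfg = CampaignConfig()
    if name == "tiny":
        cfg.system.n_solvent = 450
        cfg.system.box_edge_nm = 2.9
        cfg.ti.n_lambda = 11
        cfg.ti.lambda_spacing = "low-refined"
        cfg.ti.n_equil_steps = 600
        cfg.ti.n_prod_steps = 2000
        cfg.system.composition_grid = [0.0, 0.1, 0.2, 0.3, 0.45]
    elif name == "smoke":
        cfg.system.n_beads = 12
        cfg.system.n_solvent = 60
        cfg.system.box_edge_nm = 2.0
        cfg.ti.n_lambda = 5
        cfg.ti.n_equil_steps = 200
        cfg.ti.n_prod_steps = 600
        cfg.ti.n_equil_first_steps = 400
        cfg.ti.n_npt_steps = 1500
        cfg.system.composition_grid = [0.0, 0.25]
        cfg.umbrella.rg_min_nm = 0.35
        cfg.umbrella.rg_max_nm = 0.6
        cfg.umbrella.spacing_nm = 0.05
        cfg.umbrella.n_equil_steps = 200
        cfg.umbrella.n_prod_steps = 1000
    else:
        raise ValueError(f"unknown preset {name!r} (tiny, smoke)")
    return cfg
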