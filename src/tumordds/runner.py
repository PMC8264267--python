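"""Scenario orchestration: geometry → perfusion → transport → outcome.

Glue between the :class:`~tumordds.config.ScenarioConfig` surface and the
library modules; used by the command-line interface and the test/analysis
scripts.  All randomness flows from the single scenario seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from .config import ScenarioConfig
from .geometry import VascularNetwork, build_grid, \
    generate_synthetic_vasculature, import_vessel_mask, make_circular_tumor
from .hindered import PoreGeometry, vessel_wall_coefficients
from .params import FREE_DRUG, NORMAL, NP_PRIMARY, NP_SECONDARY, TUMOR, \
    ParameterSet, load_parameter_set
from .perfusion import couple_perfusion
from .pharmacodynamics import CourseSetup, TreatmentLedger, calibrate_dose, \
    run_cycle, run_treatment_course
from .transport import PlasmaInput, simulate_delivery

logger = logging.getLogger("tumordds")

#: interstitial NP diffusivity anchor: 20 nm particle (m²/s), scaled 1/size.
_NP_D_ANCHOR = 7e-12
_NP_D_ANCHOR_DIAMETER = 20e-9


def np_interstitial_diffusivity(diameter: float) -> float:
    """Stokes–Einstein 1/size scaling from the 20 nm literature anchor."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return _NP_D_ANCHOR * _NP_D_ANCHOR_DIAMETER / diameter


def resolve_parameters(cfg: ScenarioConfig) -> ParameterSet:
    """Literature defaults + overrides + size-resolved NP wall coefficients."""
    params = load_parameter_set(cfg.overrides or None)
    params.pore.r_o = cfg.pore_diameter / 2.0
    for key, diameter, k_rel in (
            (NP_PRIMARY, cfg.np_primary_diameter,
             cfg.k_rel if cfg.stage == 2 else cfg.k_rel1),
            (NP_SECONDARY, cfg.np_secondary_diameter, cfg.k_rel2)):
        if diameter is None:
            continue
        agent = params.agent[key]
        agent.diameter = diameter
        agent.K_rel = k_rel
        d = np_interstitial_diffusivity(diameter)
        agent.D = {NORMAL: d, TUMOR: d}
        res = vessel_wall_coefficients(
            PoreGeometry.for_particle(diameter / 2.0, params.pore),
            oversize="exclude")
        agent.P = {NORMAL: res.P, TUMOR: res.P}
        agent.sigma_f = res.sigma_f
    params.validate()
    return params


def build_geometry(cfg: ScenarioConfig, params: ParameterSet):
    """(grid, tissue, network) from the synthetic generator or a mask."""
    grid = build_grid(cfg.domain_width, cfg.domain_height, cfg.nx, cfg.ny)
    center = (cfg.domain_width / 2.0, cfg.domain_height / 2.0)
    tissue = make_circular_tumor(grid, center, cfg.tumor_radius)
    if cfg.network_csv_path:
        network = VascularNetwork.from_csv(
            Path(cfg.network_csv_path).read_text())
    elif cfg.vessel_mask_path:
        raise ValueError(
            "mask import needs an explicit boundary_spec; build the network "
            "with tumordds.geometry.import_vessel_mask and pass it via "
            "network_csv_path")
    else:
        network = generate_synthetic_vasculature(
            grid, tissue, seed=cfg.seed, n_trunk_points=cfg.n_trunk_points,
            n_sprouts=cfg.n_sprouts,
            inlet_pressure=params.vessel.P_inlet1,
            outlet_pressure=params.vessel.P_outlet)
    return grid, tissue, network


def injected_species_settings(cfg: ScenarioConfig, params: ParameterSet):
    """(drug-equivalent weight, plasma k_d) of the injected species."""
    if cfg.stage == 1:
        return 1.0, params.agent[FREE_DRUG].k_d
    if cfg.stage == 2:
        return params.agent[NP_PRIMARY].alpha, params.agent[NP_PRIMARY].k_d
    w = params.agent[NP_PRIMARY].alpha * params.agent[NP_SECONDARY].beta
    return w, params.agent[NP_PRIMARY].k_d


def calibrated_equivalent_dose(cfg: ScenarioConfig, params: ParameterSet,
                               grid, tissue, network) -> float:
    """Drug-equivalent dose C₀ anchored to the conventional first cycle.

    Runs stage 1 at unit dose on the given geometry and scales so the
    first-cycle tumor-mean kill equals ``cfg.calibration_kill``.
    """
    flow = couple_perfusion(network, grid, tissue, params)
    unit = simulate_delivery(
        1, flow, tissue, params, PlasmaInput(C0=1.0,
                                             k_d=params.agent[FREE_DRUG].k_d),
        cfg.t_end, dt0=cfg.dt0, steps_per_phase=cfg.steps_per_phase)
    c0 = calibrate_dose(unit, params.agent[FREE_DRUG].omega,
                        cfg.calibration_kill)
    logger.info("calibrated drug-equivalent dose C0 = %.6g mol/m3", c0)
    return c0


def make_setup(cfg: ScenarioConfig, params: ParameterSet, grid, tissue,
               network, c0_equivalent: float | None = None) -> CourseSetup:
    weight, k_d = injected_species_settings(cfg, params)
    if c0_equivalent is None:
        c0_equivalent = cfg.c0
    if c0_equivalent is None:
        c0_equivalent = calibrated_equivalent_dose(cfg, params, grid, tissue,
                                                   network)
    return CourseSetup(
        grid=grid, network=network, params=params, plasma_kd=k_d,
        injected_c0=c0_equivalent / weight, t_end=cfg.t_end,
        free_drug_vascular_exchange=cfg.free_drug_vascular_exchange,
        np_lymphatic_drainage=cfg.np_lymphatic_drainage,
        dt0=cfg.dt0, steps_per_phase=cfg.steps_per_phase)


def run_single_delivery(cfg: ScenarioConfig):
    """One perfusion + delivery run; returns (flow, result, setup)."""
    cfg.validate()
    params = resolve_parameters(cfg)
    grid, tissue, network = build_geometry(cfg, params)
    setup = make_setup(cfg, params, grid, tissue, network)
    flow, result = run_cycle(cfg.stage, setup, tissue)
    return flow, result, setup


def run_course(cfg: ScenarioConfig) -> TreatmentLedger:
    """Full multi-cycle treatment course for the configured stage."""
    cfg.validate()
    params = resolve_parameters(cfg)
    grid, tissue, network = build_geometry(cfg, params)
    setup = make_setup(cfg, params, grid, tissue, network)
    return run_treatment_course(cfg.stage, setup, tissue, cfg.n_cycles,
                                cfg.break_months)


def config_hash(cfg: ScenarioConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def summarize_delivery(cfg: ScenarioConfig, flow, result) -> dict:
    """Machine-readable run summary (deterministic for a fixed config+seed)."""
    from .params import pressure_to_mmhg
    from .pharmacodynamics import fraction_killed, tumor_survival

    omega = result.system.params.agent[FREE_DRUG].omega
    fkc = fraction_killed(result.final.C_INT, omega)
    mask = result.system.tissue.tumor_mask
    return {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "stage": cfg.stage,
        "mean_tumor_ifp_mmhg": pressure_to_mmhg(float(flow.P_i[mask].mean())),
        "mean_normal_ifp_mmhg": pressure_to_mmhg(
            float(flow.P_i[~mask].mean())),
        "tumor_mean_c_int": result.tumor_mean("INT"),
        "normal_mean_c_int": result.normal_mean("INT"),
        "tumor_mean_fkc": float(fkc[mask].mean()),
        "survival_fraction": tumor_survival(fkc, result.system.tissue),
        "mass_balance_relative_error": result.balance.relative_error,
        "perfusion_iterations": flow.iterations,
    }


def sweep_release_rates(cfg: ScenarioConfig, rates, diameters=None
                        ) -> list[dict]:
    """Tumor-mean FKC over a (release rate × NP size) grid, two-stage.

    Geometry, perfusion and the calibrated dose are shared across the sweep;
    only the NP design (size → wall coefficients, K_rel) changes.
    """
    from .pharmacodynamics import fraction_killed

    base = ScenarioConfig.from_dict({**cfg.to_dict(), "stage": 2})
    params0 = resolve_parameters(base)
    grid, tissue, network = build_geometry(base, params0)
    if base.c0 is not None:
        c0 = base.c0
    else:
        c0 = calibrated_equivalent_dose(base, params0, grid, tissue, network)
    rows = []
    for d in (diameters or [base.np_primary_diameter]):
        for rate in rates:
            cfg_i = ScenarioConfig.from_dict({
                **base.to_dict(), "np_primary_diameter": float(d),
                "k_rel": float(rate), "c0": c0})
            params = resolve_parameters(cfg_i)
            setup = make_setup(cfg_i, params, grid, tissue, network, c0)
            _, result = run_cycle(2, setup, tissue)
            omega = params.agent[FREE_DRUG].omega
            fkc = fraction_killed(result.final.C_INT, omega)
            rows.append({
                "np_diameter_nm": float(d) * 1e9,
                "k_rel_per_s": float(rate),
                "tumor_mean_fkc": float(fkc[tissue.tumor_mask].mean()),
                "tumor_mean_c_int": result.tumor_mean("INT"),
            })
            logger.info("sweep d=%.0fnm k_rel=%.2e -> FKC=%.4f",
                        d * 1e9, rate, rows[-1]["tumor_mean_fkc"])
    return rows
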