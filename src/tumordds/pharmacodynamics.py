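"""Cell-kill pharmacodynamics and multi-cycle treatment evaluation.

Internalized drug exposure maps to a fraction of killed cells through the
empirical doxorubicin kill law FKC = 1 − exp(−ω·C_INT).  The surviving
tumor-cell count regrows between treatment cycles by Gompertz's law

    n(t) = N·exp{ln(N∞/N)·[1 − exp(−b·t)]},

and a treatment course alternates delivery simulations (on the current,
shrinking tumor geometry) with drug-free breaks, recording per-cycle
efficacies and regrowths as percentages of the initial cell count N₀.
Healthy tissue is tracked with the same kill law and half the growth rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .geometry import SimulationGrid, TissueMap, VascularNetwork
from .params import ParameterSet
from .perfusion import FlowSolution, couple_perfusion
from .transport import DeliveryResult, PlasmaInput, simulate_delivery


def fraction_killed(C_INT, omega: float):
    """FKC = 1 − exp(−ω·C_INT), elementwise; C_INT must be ≥ 0."""
    c = np.asarray(C_INT, dtype=float)
    if np.any(c < 0):
        raise ValueError("C_INT must be >= 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    out = -np.expm1(-omega * c)
    return float(out) if out.ndim == 0 else out


def tumor_survival(fkc: np.ndarray, tissue: TissueMap) -> float:
    """Surviving fraction S_F: area-weighted mean of (1 − FKC) over tumor."""
    mask = tissue.tumor_mask
    if not mask.any():
        raise ValueError("tumor region is empty")
    return float((1.0 - np.asarray(fkc))[mask].mean())


def gompertz_regrowth(N_i: float, t: float, N_inf: float, b: float) -> float:
    """Gompertz cell count after a drug-free interval of t months."""
    if N_i <= 0:
        raise ValueError("N_i must be > 0")
    if N_i > N_inf:
        raise ValueError("N_i exceeds the carrying capacity N_inf")
    if t < 0:
        raise ValueError("t must be >= 0")
    return N_i * math.exp(math.log(N_inf / N_i) * (1.0 - math.exp(-b * t)))


def ledger_from_percentages(efficacies_pct, regrowths_pct) -> np.ndarray:
    """Survivor trajectory (percent of N₀) from per-cycle percentages.

    Starting at 100, each treatment subtracts its efficacy and each
    inter-cycle break adds its regrowth, both expressed as percent of the
    initial count.  Returns the full alternating trajectory
    ``[100, after T1, after B1, after T2, ...]``.
    """
    eff = [float(e) for e in efficacies_pct]
    reg = [float(r) for r in regrowths_pct]
    if len(reg) != len(eff) - 1:
        raise ValueError("need exactly one fewer regrowth than efficacies")
    if any(e < 0 for e in eff) or any(r < 0 for r in reg):
        raise ValueError("percentages must be >= 0")
    traj = [100.0]
    for k, e in enumerate(eff):
        traj.append(traj[-1] - e)
        if traj[-1] < 0:
            raise ValueError(f"survivor went negative after treatment {k + 1}")
        if k < len(reg):
            traj.append(traj[-1] + reg[k])
    return np.asarray(traj)


# --------------------------------------------------------------------------
# Treatment course
# --------------------------------------------------------------------------

@dataclass
class CycleRecord:
    cycle: int
    tumor_radius: float          # m, geometry used this cycle
    n_pre: float                 # tumor cells before treatment
    mean_fkc: float              # tumor-mean fraction of killed cells
    survival_fraction: float     # S_F
    n_post: float                # after treatment
    n_regrown: float             # after the drug-free break
    efficacy_pct: float          # (n_pre − n_post)/N0 × 100
    regrowth_pct: float          # (n_regrown − n_post)/N0 × 100
    healthy_mean_fkc: float
    n_healthy: float             # healthy cells after break


@dataclass
class TreatmentLedger:
    """Per-cycle bookkeeping of one treatment course."""

    stage: int
    N0: float
    break_months: float
    cycles: list[CycleRecord] = field(default_factory=list)

    def survivor_trajectory(self) -> np.ndarray:
        """Alternating survivor percentages of N₀ (as in the printed ledgers)."""
        return ledger_from_percentages(
            [c.efficacy_pct for c in self.cycles],
            [c.regrowth_pct for c in self.cycles[:-1]])

    def cumulative_kill_pct(self, n_cycles: int | None = None) -> float:
        """Percent of N₀ killed right after treatment ``n_cycles``."""
        cyc = self.cycles[: n_cycles or len(self.cycles)]
        if not cyc:
            return 0.0
        return 100.0 * (1.0 - cyc[-1].n_post / self.N0)

    def to_json(self) -> str:
        return json.dumps({"stage": self.stage, "N0": self.N0,
                           "break_months": self.break_months,
                           "cycles": [asdict(c) for c in self.cycles]},
                          indent=2)

    def to_rows(self) -> list[dict]:
        return [asdict(c) for c in self.cycles]


def calibrate_dose(unit_result: DeliveryResult, omega: float,
                   target_kill: float) -> float:
    """Dose C₀ whose tumor-mean FKC equals ``target_kill``.

    Exploits linearity: a delivery run at unit dose yields the per-cell
    exposure field c_i = C_INT per unit C₀, so the tumor-mean surviving
    fraction is mean exp(−ω·C₀·c_i), a strictly decreasing function of C₀
    solved by bracketing.
    """
    if not 0.0 < target_kill < 1.0:
        raise ValueError("target_kill must be in (0,1)")
    mask = unit_result.system.tissue.tumor_mask
    c_unit = unit_result.final.C_INT[mask]
    if c_unit.max() <= 0:
        raise ValueError("no tumor exposure at unit dose; cannot calibrate")

    def mean_kill(c0: float) -> float:
        return float(-np.expm1(-omega * c0 * c_unit).mean())

    lo, hi = 1e-12, 1.0
    while mean_kill(hi) < target_kill:
        hi *= 10.0
        if hi > 1e12:
            raise RuntimeError("dose calibration failed to bracket")
    return float(brentq(lambda c0: mean_kill(c0) - target_kill, lo, hi,
                        xtol=1e-14, rtol=1e-12))


@dataclass
class CourseSetup:
    """Everything needed to run one delivery cycle on a given geometry."""

    grid: SimulationGrid
    network: VascularNetwork
    params: ParameterSet
    plasma_kd: float             # s, circulation decay of injected species
    injected_c0: float           # mol/m³ of the injected species
    t_end: float                 # s, exposure window per cycle
    free_drug_vascular_exchange: bool = False
    np_lymphatic_drainage: bool = True
    dt0: float = 0.25
    steps_per_phase: int = 48


def run_cycle(stage: int, setup: CourseSetup, tissue: TissueMap
              ) -> tuple[FlowSolution, DeliveryResult]:
    """Perfusion + delivery on the current geometry."""
    flow = couple_perfusion(setup.network, setup.grid, tissue, setup.params)
    plasma = PlasmaInput(C0=setup.injected_c0, k_d=setup.plasma_kd)
    result = simulate_delivery(
        stage, flow, tissue, setup.params, plasma, setup.t_end,
        dt0=setup.dt0, steps_per_phase=setup.steps_per_phase,
        free_drug_vascular_exchange=setup.free_drug_vascular_exchange,
        np_lymphatic_drainage=setup.np_lymphatic_drainage)
    return flow, result


def run_treatment_course(stage: int, setup: CourseSetup, tissue: TissueMap,
                         n_cycles: int, break_months: float,
                         geometry_coupling: bool = True) -> TreatmentLedger:
    """Multi-cycle course with Gompertz regrowth over drug-free breaks.

    Per cycle: solve perfusion and delivery on the current geometry, apply
    the kill law to the internalized-drug field, shrink the tumor by the
    2D area rule (unless ``geometry_coupling`` is off), and regrow both the
    tumor (rate b) and healthy tissue (rate b/2) over the break.  Efficacy
    and regrowth are recorded as percent of the initial count N₀.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    gp = setup.params.gompertz
    omega = setup.params.agent["free_drug"].omega
    N = gp.N0
    N_healthy = gp.N_healthy
    ledger = TreatmentLedger(stage=stage, N0=gp.N0,
                             break_months=break_months)
    current = tissue
    if geometry_coupling and (tissue.tumor_center is None
                              or tissue.tumor_radius is None):
        raise ValueError("geometry coupling requires a circular tumor")
    radius0 = tissue.tumor_radius
    for cycle in range(1, n_cycles + 1):
        _, result = run_cycle(stage, setup, current)
        fkc = fraction_killed(result.final.C_INT, omega)
        s_f = tumor_survival(fkc, current)
        n_pre = N
        n_post = s_f * n_pre
        healthy_fkc = float(fkc[~current.tumor_mask].mean())
        N_healthy_post = N_healthy * (1.0 - healthy_fkc)
        n_regrown = gompertz_regrowth(n_post, break_months, gp.N_inf, gp.b)
        N_healthy = gompertz_regrowth(N_healthy_post, break_months,
                                      gp.N_healthy, gp.b / 2.0)
        ledger.cycles.append(CycleRecord(
            cycle=cycle,
            tumor_radius=current.tumor_radius or math.nan,
            n_pre=n_pre,
            mean_fkc=float(fkc[current.tumor_mask].mean()),
            survival_fraction=s_f,
            n_post=n_post,
            n_regrown=n_regrown,
            efficacy_pct=100.0 * (n_pre - n_post) / gp.N0,
            regrowth_pct=100.0 * (n_regrown - n_post) / gp.N0,
            healthy_mean_fkc=healthy_fkc,
            n_healthy=N_healthy,
        ))
        N = n_regrown
        if geometry_coupling:
            # area ∝ cell number, anchored to the initial radius so growth
            # past N0 (e.g. a zero-dose cycle) is representable too
            from .geometry import make_circular_tumor
            current = make_circular_tumor(
                setup.grid, tissue.tumor_center,
                radius0 * math.sqrt(N / gp.N0))
    return ledger
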