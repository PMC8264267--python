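"""Kill law, Gompertz regrowth, treatment-ledger arithmetic, course runs."""

import numpy as np
import pytest

from tumordds.geometry import build_grid, make_circular_tumor
from tumordds.pharmacodynamics import CourseSetup, calibrate_dose, \
    fraction_killed, gompertz_regrowth, ledger_from_percentages, \
    run_treatment_course, tumor_survival
from tumordds.transport import PlasmaInput, simulate_delivery

#: per-cycle conventional-chemotherapy efficacies (percent of N0), cycles
#: 1..10, and the regrowth over each of the nine inter-cycle breaks
CONVENTIONAL_EFFICACIES = [36.78, 29.67, 24.41, 20.24, 14.9,
                           5.9, 4.65, 3.42, 2.73, 2.11]
CONVENTIONAL_REGROWTHS = [13.28, 10.57, 8.06, 5.59, 3.4,
                          2.85, 2.4, 2.17, 2.03]


class TestFractionKilled:
    def test_values(self):
        assert fraction_killed(0.0, 0.6603) == 0.0
        # 1 − e^(−0.6603) for 1 mol/m³ at the doxorubicin kill constant
        assert fraction_killed(1.0, 0.6603) == pytest.approx(0.48330,
                                                             abs=1e-5)
        assert fraction_killed(1e6, 0.6603) == pytest.approx(1.0)

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            fraction_killed(-0.1, 0.6603)

    def test_increasing_and_concave(self):
        c = np.linspace(0, 5, 50)
        f = fraction_killed(c, 0.6603)
        assert np.all(np.diff(f) > 0)
        assert np.all(np.diff(f, 2) < 0)


class TestTumorSurvival:
    def test_uniform_and_mixed_fields(self):
        grid = build_grid(1e-3, 1e-3, 10, 10)
        tissue = make_circular_tumor(grid, (5e-4, 5e-4), 3.5e-4)
        fkc = np.full((10, 10), 0.25)
        assert tumor_survival(fkc, tissue) == pytest.approx(0.75)
        assert tumor_survival(np.ones((10, 10)), tissue) == 0.0
        # half the tumor killed at 0.8, half at 0.2
        half = np.full((10, 10), 0.8)
        half[:, :5] = 0.2
        left = tissue.tumor_mask[:, :5].sum()
        right = tissue.tumor_mask[:, 5:].sum()
        expected = 1 - (0.2 * left + 0.8 * right) / (left + right)
        assert tumor_survival(half, tissue) == pytest.approx(expected)

    def test_empty_tumor_rejected(self):
        grid = build_grid(1e-3, 1e-3, 10, 10)
        tissue = make_circular_tumor(grid, (5e-4, 5e-4), 0.0)
        with pytest.raises(ValueError):
            tumor_survival(np.zeros((10, 10)), tissue)


class TestGompertz:
    def test_limits(self):
        assert gompertz_regrowth(5e9, 0.0, 3.1e12, 0.0283) == 5e9
        assert gompertz_regrowth(5e9, 1e9, 3.1e12, 0.0283) == \
            pytest.approx(3.1e12, rel=1e-6)

    def test_one_month_value(self):
        # N0 = 5e9, N_inf = 3.1e12, b = 0.0283/month, frozen oracle value
        assert gompertz_regrowth(5e9, 1.0, 3.1e12, 0.0283) == \
            pytest.approx(5.982559e9, rel=1e-6)

    def test_monotone_in_time_and_rate(self):
        ts = [gompertz_regrowth(5e9, t, 3.1e12, 0.0283)
              for t in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(ts, ts[1:]))
        bs = [gompertz_regrowth(5e9, 1.0, 3.1e12, b)
              for b in (0.01, 0.0283, 0.1)]
        assert all(a < b for a, b in zip(bs, bs[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gompertz_regrowth(0.0, 1.0, 3.1e12, 0.0283)
        with pytest.raises(ValueError):
            gompertz_regrowth(4e12, 1.0, 3.1e12, 0.0283)
        with pytest.raises(ValueError):
            gompertz_regrowth(5e9, -1.0, 3.1e12, 0.0283)


class TestLedgerArithmetic:
    def test_single_treatment(self):
        assert ledger_from_percentages([50.0], [])[-1] == 50.0

    def test_conventional_course_survivors(self):
        """The published per-cycle percentages compose to the published
        cumulative figures: 11.50% survivors after 5 cycles, 5.54% after
        all 10 (i.e. 88.50% and 94.46% killed)."""
        traj5 = ledger_from_percentages(CONVENTIONAL_EFFICACIES[:5],
                                        CONVENTIONAL_REGROWTHS[:4])
        assert traj5[-1] == pytest.approx(11.50, abs=5e-3)
        traj10 = ledger_from_percentages(CONVENTIONAL_EFFICACIES,
                                         CONVENTIONAL_REGROWTHS)
        assert traj10[-1] == pytest.approx(5.54, abs=5e-3)
        assert 100.0 - traj10[-1] == pytest.approx(94.46, abs=5e-3)

    def test_trajectory_alternates(self):
        traj = ledger_from_percentages([10.0, 10.0], [4.0])
        assert list(traj) == pytest.approx([100.0, 90.0, 94.0, 84.0])

    def test_validation(self):
        with pytest.raises(ValueError):
            ledger_from_percentages([10.0, 10.0], [])
        with pytest.raises(ValueError):
            ledger_from_percentages([60.0, 60.0], [5.0])
        with pytest.raises(ValueError):
            ledger_from_percentages([-1.0], [])


class TestDoseCalibration:
    def test_calibrated_dose_hits_target_kill(self, baseline, baseline_flow):
        res = simulate_delivery(1, baseline_flow, baseline["tissue"],
                                baseline["params"],
                                PlasmaInput(C0=1.0, k_d=360.0), 24 * 3600.0)
        omega = baseline["params"].agent["free_drug"].omega
        c0 = calibrate_dose(res, omega, 0.30)
        mask = baseline["tissue"].tumor_mask
        kill = -np.expm1(-omega * c0 * res.final.C_INT[mask]).mean()
        assert kill == pytest.approx(0.30, abs=1e-9)

    def test_rejects_unreachable_target(self, baseline, baseline_flow):
        res = simulate_delivery(1, baseline_flow, baseline["tissue"],
                                baseline["params"],
                                PlasmaInput(C0=0.0, k_d=360.0), 3600.0)
        with pytest.raises(ValueError):
            calibrate_dose(res, 0.6603, 0.5)


@pytest.fixture(scope="module")
def course_setup():
    """Tiny, fast course configuration shared by the course tests."""
    from tumordds.config import ScenarioConfig
    from tumordds.runner import build_geometry, resolve_parameters

    cfg = ScenarioConfig(stage=1, nx=32, ny=32, seed=3, t_end=6 * 3600.0)
    params = resolve_parameters(cfg)
    grid, tissue, network = build_geometry(cfg, params)
    return cfg, params, grid, tissue, network


class TestTreatmentCourse:
    def test_zero_dose_cycle_is_pure_gompertz(self, course_setup):
        cfg, params, grid, tissue, network = course_setup
        setup = CourseSetup(grid=grid, network=network, params=params,
                            plasma_kd=360.0, injected_c0=0.0,
                            t_end=cfg.t_end)
        ledger = run_treatment_course(1, setup, tissue, n_cycles=1,
                                      break_months=1.0)
        rec = ledger.cycles[0]
        gp = params.gompertz
        assert rec.efficacy_pct == 0.0
        expected = gompertz_regrowth(gp.N0, 1.0, gp.N_inf, gp.b)
        assert rec.n_regrown == pytest.approx(expected, rel=1e-12)

    def test_course_bookkeeping_identity(self, course_setup):
        """Survivor % after cycle k = 100 − Σ efficacies + Σ regrowths."""
        cfg, params, grid, tissue, network = course_setup
        setup = CourseSetup(grid=grid, network=network, params=params,
                            plasma_kd=360.0, injected_c0=1.0,
                            t_end=cfg.t_end)
        ledger = run_treatment_course(1, setup, tissue, n_cycles=3,
                                      break_months=1.0)
        gp = params.gompertz
        for k, rec in enumerate(ledger.cycles, start=1):
            explicit = (100.0
                        - sum(c.efficacy_pct for c in ledger.cycles[:k])
                        + sum(c.regrowth_pct for c in ledger.cycles[:k - 1]))
            assert 100.0 * rec.n_post / gp.N0 == pytest.approx(explicit)
        assert np.all(np.diff([c.n_pre for c in ledger.cycles]) < 0)

    def test_decoupled_geometry_gives_identical_cycles(self, course_setup):
        cfg, params, grid, tissue, network = course_setup
        setup = CourseSetup(grid=grid, network=network, params=params,
                            plasma_kd=360.0, injected_c0=1.0,
                            t_end=cfg.t_end)
        ledger = run_treatment_course(1, setup, tissue, n_cycles=2,
                                      break_months=1.0,
                                      geometry_coupling=False)
        s = [c.survival_fraction for c in ledger.cycles]
        assert s[0] == s[1]     # same geometry → identical kill per cycle

    def test_shrinking_tumor_radius(self, course_setup):
        cfg, params, grid, tissue, network = course_setup
        setup = CourseSetup(grid=grid, network=network, params=params,
                            plasma_kd=360.0, injected_c0=2.0,
                            t_end=cfg.t_end)
        ledger = run_treatment_course(1, setup, tissue, n_cycles=2,
                                      break_months=1.0)
        assert ledger.cycles[1].tumor_radius < ledger.cycles[0].tumor_radius
        expected = tissue.tumor_radius * np.sqrt(
            ledger.cycles[0].n_regrown / params.gompertz.N0)
        assert ledger.cycles[1].tumor_radius == pytest.approx(expected)
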