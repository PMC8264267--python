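"""Drug transport: plasma forcing, Patlak flux, CDR integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tumordds.geometry import TissueMap, build_grid
from tumordds.params import FREE_DRUG, NP_PRIMARY, NP_SECONDARY, \
    convert_pressure, load_parameter_set
from tumordds.transport import PlasmaInput, make_uniform_flow, \
    patlak_coefficients, plasma_concentration, lymphatic_solute_sink, \
    simulate_delivery, time_schedule, transvascular_solute_flux


class TestPlasma:
    def test_bolus_decay(self):
        p = PlasmaInput(C0=2.0, k_d=360.0)
        assert plasma_concentration(0.0, p) == 2.0
        assert plasma_concentration(360.0, p) == pytest.approx(2.0 / np.e)
        # free doxorubicin at twice its plasma e-folding time
        assert plasma_concentration(720.0, p) == \
            pytest.approx(2.0 * 0.13534, rel=1e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            plasma_concentration(-1.0, PlasmaInput(C0=1.0, k_d=1.0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            PlasmaInput(C0=-1.0, k_d=1.0)
        with pytest.raises(ValueError):
            PlasmaInput(C0=1.0, k_d=0.0)


class TestPatlakFlux:
    def test_small_peclet_limit(self):
        """Pe → 0: Φ_B → ϕ_B(1−σ_f)C_p + P·S/V·(C_p − C_f)."""
        phi_B, sigma_f, P, sv = 1e-12, 0.35, 3e-6, 1e4
        flux = transvascular_solute_flux(phi_B, sigma_f, P, sv, 1.0, 0.3)
        assert flux == pytest.approx(phi_B * 0.65 + P * sv * 0.7, rel=1e-6)

    def test_unit_peclet_factor(self):
        """At Pe = 1 the diffusive weight is 1/(e−1) = 0.58198."""
        P, sv = 3e-6, 1e4
        phi_B = P * sv / (1 - 0.35)      # makes Pe exactly 1
        flux = transvascular_solute_flux(phi_B, 0.35, P, sv, 1.0, 0.0)
        expected = phi_B * 0.65 + P * sv * (1 / (np.e - 1))
        assert flux == pytest.approx(expected, rel=1e-9)
        assert 1 / (np.e - 1) == pytest.approx(0.58198, abs=1e-5)

    def test_convection_dominated_limit(self):
        phi_B = 1.0     # enormous filtration
        flux = transvascular_solute_flux(phi_B, 0.35, 3e-6, 1e4, 1.0, 5.0)
        assert flux == pytest.approx(phi_B * 0.65, rel=1e-6)

    def test_no_vessels_no_flux(self):
        assert transvascular_solute_flux(0.0, 0.35, 3e-6, 0.0, 1.0, 0.5) == 0

    def test_series_matches_exact_across_switch(self):
        pe = np.array([-1e-5, -1e-7, 1e-7, 1e-5, 1e-3])
        P, sv, sf = 3e-6, 1e4, 0.0
        phi = pe * P * sv
        influx, efflux = patlak_coefficients(phi, sf, P, sv)
        exact = pe / np.expm1(pe)
        assert efflux == pytest.approx(P * sv * exact, rel=1e-9)

    def test_reabsorption_is_total_function(self):
        """ϕ_B < 0 drains tissue concentration, never injects negatively."""
        influx, efflux = patlak_coefficients(-1e-6, 0.35, 3e-6, 1e4)
        assert influx >= 0 and efflux > 0
        influx0, efflux0 = patlak_coefficients(-1e-6, 0.35, 0.0, 1e4)
        assert influx0 == 0 and efflux0 == pytest.approx(1e-6 * 0.65)

    def test_lymphatic_sink(self):
        assert lymphatic_solute_sink(1e-4, 2.0) == pytest.approx(2e-4)
        assert lymphatic_solute_sink(0.0, 5.0) == 0.0
        assert lymphatic_solute_sink(1e-4, 0.0) == 0.0


@pytest.fixture(scope="module")
def quiescent():
    """Uniformly vascularized all-tumor block with zero interstitial flow."""
    params = load_parameter_set()
    grid = build_grid(4e-4, 4e-4, 8, 8)
    tissue = TissueMap(tumor_mask=np.ones((8, 8), dtype=bool))
    flow = make_uniform_flow(grid, tissue, params, sv_value=2e4,
                             P_B=convert_pressure(20.0))
    return params, grid, tissue, flow


class TestKinetics0D:
    def test_bound_free_ratio_reaches_binding_equilibrium(self, quiescent):
        """Quasi-steady C_B/C_F = (K_ON C_rec/φ)/(K_OFF + K_INT)."""
        params, grid, tissue, flow = quiescent
        plasma = PlasmaInput(C0=1.0, k_d=1e9)   # essentially constant source
        res = simulate_delivery(1, flow, tissue, params, plasma,
                                t_end=5000.0)
        fd = params.agent[FREE_DRUG]
        expected = fd.binding_rate() / (fd.K_OFF + fd.K_INT)
        ratio = res.final.C_B / res.final.C_F
        assert expected == pytest.approx(0.375 / 8.05e-3, rel=1e-9)
        assert np.abs(ratio / expected - 1).max() < 1e-3

    def test_matches_independent_ode_integration(self, quiescent):
        """Full trajectory vs an independent stiff ODE solve of the 0D system."""
        params, grid, tissue, flow = quiescent
        plasma = PlasmaInput(C0=1.0, k_d=360.0)
        t_end = 4 * 3600.0
        t_mid = 1800.0      # bound drug near its peak here
        res = simulate_delivery(1, flow, tissue, params, plasma, t_end,
                                dt0=0.1, steps_per_phase=40, dt_max=20.0,
                                output_times=[t_mid])
        fd = params.agent[FREE_DRUG]
        influx, efflux = patlak_coefficients(
            float(flow.phi_B[0, 0]), fd.sigma_f, fd.P["tumor"],
            float(flow.sv[0, 0]))
        kon, koff, kint = fd.binding_rate(), fd.K_OFF, fd.K_INT

        def rhs(t, y):
            cf, cb, cint = y
            cp = plasma.C0 * np.exp(-t / plasma.k_d)
            return [influx * cp - efflux * cf - kon * cf + koff * cb,
                    kon * cf - (koff + kint) * cb,
                    kint * cb]

        sol = solve_ivp(rhs, (0, t_end), [0, 0, 0], method="BDF",
                        rtol=1e-9, atol=1e-16, t_eval=[t_mid, t_end])
        assert res.final.C_INT[0, 0] == pytest.approx(sol.y[2, -1], rel=0.01)
        mid = next(s for s in res.states if s.t == t_mid)
        assert mid.C_B[0, 0] == pytest.approx(sol.y[1, 0], rel=0.02)
        assert mid.C_F[0, 0] == pytest.approx(sol.y[0, 0], rel=0.02)


class TestDeliverySimulation:
    def test_zero_dose_stays_zero(self, baseline, baseline_flow):
        res = simulate_delivery(1, baseline_flow, baseline["tissue"],
                                baseline["params"],
                                PlasmaInput(C0=0.0, k_d=360.0), 3600.0)
        for name in ("F", "B", "INT"):
            assert not res.final.field(name).any()

    def test_tumor_concentration_exceeds_normal(self, baseline,
                                                baseline_flow):
        """Stage 1: tumor-mean total drug above normal-tissue mean."""
        res = simulate_delivery(1, baseline_flow, baseline["tissue"],
                                baseline["params"],
                                PlasmaInput(C0=1.0, k_d=360.0), 24 * 3600.0)
        w = res.system.weights
        total = res.final.total_drug_equivalent(w)
        mask = baseline["tissue"].tumor_mask
        assert total[mask].mean() > total[~mask].mean()

    def test_nonnegative_and_conservative_all_stages(self, baseline,
                                                     baseline_flow):
        from tumordds.config import ScenarioConfig
        from tumordds.runner import resolve_parameters

        for stage in (1, 2, 3):
            params = resolve_parameters(ScenarioConfig(stage=stage))
            res = simulate_delivery(stage, baseline_flow, baseline["tissue"],
                                    params,
                                    PlasmaInput(C0=1.0, k_d=1320 * 60.0),
                                    12 * 3600.0,
                                    output_times=[3600.0, 6 * 3600.0])
            for state in res.states:
                for name in ("N1", "N2", "F", "B", "INT"):
                    assert state.field(name).min() >= 0.0
            assert res.balance.relative_error < 1e-3
            assert res.balance.influx > 0

    def test_stage2_without_release_frees_no_drug(self, baseline,
                                                  baseline_flow):
        ps = load_parameter_set({"agent.np_primary.K_rel": 0.0,
                                 "agent.np_primary.P": {"normal": 4e-10,
                                                        "tumor": 4e-10},
                                 "agent.np_primary.sigma_f": 0.04})
        res = simulate_delivery(2, baseline_flow, baseline["tissue"], ps,
                                PlasmaInput(C0=1.0, k_d=1320 * 60.0),
                                6 * 3600.0)
        assert res.final.C_N1.max() > 0
        for name in ("F", "B", "INT"):
            assert not res.final.field(name).any()

    def test_stage3_fast_primary_release_matches_stage2(self, baseline,
                                                        baseline_flow):
        """K_rel1 → ∞ collapses the three-stage chain onto two stages."""
        ps3 = load_parameter_set()
        ps3.agent[NP_PRIMARY].P = {"normal": 4e-10, "tumor": 4e-10}
        ps3.agent[NP_PRIMARY].sigma_f = 0.043
        ps3.agent[NP_PRIMARY].K_rel = 1e3
        res3 = simulate_delivery(3, baseline_flow, baseline["tissue"], ps3,
                                 PlasmaInput(C0=1.0, k_d=1320 * 60.0),
                                 12 * 3600.0)
        # stage-2 comparator: same injection, payload α·β, secondary's
        # tissue transport and release kinetics
        ps2 = load_parameter_set()
        alpha = ps2.agent[NP_PRIMARY].alpha
        beta = ps2.agent[NP_SECONDARY].beta
        ps2.agent[NP_PRIMARY].P = {"normal": 4e-10, "tumor": 4e-10}
        ps2.agent[NP_PRIMARY].sigma_f = 0.043
        ps2.agent[NP_PRIMARY].alpha = alpha * beta
        ps2.agent[NP_PRIMARY].K_rel = ps2.agent[NP_SECONDARY].K_rel
        ps2.agent[NP_PRIMARY].D = dict(ps2.agent[NP_SECONDARY].D)
        res2 = simulate_delivery(2, baseline_flow, baseline["tissue"], ps2,
                                 PlasmaInput(C0=1.0, k_d=1320 * 60.0),
                                 12 * 3600.0)
        m3 = res3.tumor_mean("INT")
        m2 = res2.tumor_mean("INT")
        assert m3 == pytest.approx(m2, rel=0.02)

    def test_temporal_convergence(self, baseline, baseline_flow):
        """Halving every time step moves tumor-mean C_INT by < 0.5%."""
        vals = []
        for refine in (0, 1):
            res = simulate_delivery(1, baseline_flow, baseline["tissue"],
                                    baseline["params"],
                                    PlasmaInput(C0=1.0, k_d=360.0),
                                    12 * 3600.0, refine=refine)
            vals.append(res.tumor_mean("INT"))
        assert abs(vals[1] / vals[0] - 1) < 0.005


class TestTimeSchedule:
    def test_monotone_and_exact_endpoints(self):
        ts = time_schedule(1000.0, dt0=0.5, output_times=[100.0, 321.5])
        assert ts[0] == 0.0 and ts[-1] == 1000.0
        assert np.all(np.diff(ts) > 0)
        assert 100.0 in ts and 321.5 in ts

    def test_rejects_outputs_beyond_horizon(self):
        with pytest.raises(ValueError):
            time_schedule(10.0, output_times=[20.0])
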