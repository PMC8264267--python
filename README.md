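# tumordds

Image-based, multi-scale simulation of drug delivery to vascularized solid
tumors: coupled capillary-network / interstitial fluid flow, one-, two- and
three-stage convection–diffusion–reaction drug transport with size-dependent
nanoparticle vessel-wall coefficients, cell-kill pharmacodynamics, and
multi-cycle treatment evaluation with Gompertz regrowth.

**Who it is for.** Computational pharmacologists and modelers asking how
nanocarrier design — particle size relative to the vessel-wall pore size,
release-rate kinetics, staging — changes drug exposure and tumor-cell kill in
a perfused tumor, compared with conventional (free-drug) chemotherapy.

## The model in brief

A 2D tissue domain holds a central circular tumor perfused by a capillary
graph (synthetic, with two parent-vessel inlets at 25 mmHg and one outlet at
10 mmHg, or imported from a segmented vessel mask). Blood flow is Poiseuille
flow with a Starling transmural leak; the interstitium is a Darcy medium:

    v_i = −κ∇P_i,   −κ∇²P_i = L_p(S/V)(P_B − P_i − σ_s(π_B−π_i)) − L_pL(S/V)_L(P_i − P_L)

Tumor tissue is leaky and lymphatic-free, producing the elevated interstitial
fluid pressure (IFP) plateau that hinders convective delivery. On the
converged flow field, drug compartments C_N1, C_N2, C_F, C_B, C_INT evolve
by convection–diffusion–reaction: carriers release payload (α, β molecules at
rates K_rel1, K_rel2), free drug binds at (1/φ)K_ON·C_rec, unbinds at K_OFF
and is internalized at K_INT. The injected species enters from plasma
(C_p = C₀e^(−t/k_d)) through the Patlak transvascular flux

    Φ_B = ϕ_B(1−σ_f)C_p + P(S/V)(C_p − C_f)·Pe/(e^Pe − 1)

with σ_f, P for nanoparticles computed from hindered transport through
cylindrical wall pores (Bungay–Brenner hindrance factors H, W; λ = r_s/r_o).
Kill follows the empirical doxorubicin law FKC = 1 − exp(−ω·C_INT);
treatment courses alternate delivery cycles with drug-free breaks under
Gompertz regrowth n(t) = N·exp{ln(N∞/N)[1 − e^(−bt)]}. See
[docs/methods.md](docs/methods.md) for assumptions, parameters and numerics.

## Worked example

One conventional-chemotherapy delivery (stage 1) on the synthetic baseline —
2 mm domain, 64×64 grid, 0.5 mm tumor, seeded network, 96 h exposure at
1 mol/m³ plasma dose:

```python
from tumordds import ScenarioConfig
from tumordds.runner import run_single_delivery, summarize_delivery
import json

cfg = ScenarioConfig(stage=1, seed=1, c0=1.0, nx=64, ny=64)
flow, result, setup = run_single_delivery(cfg)
print(json.dumps(summarize_delivery(cfg, flow, result), indent=2))
```

prints

```json
{
  "config_hash": "b54dd41420ba8f59",
  "seed": 1,
  "stage": 1,
  "mean_tumor_ifp_mmhg": 10.282454302490637,
  "mean_normal_ifp_mmhg": 2.4751974473083784,
  "tumor_mean_c_int": 0.7055000829223473,
  "normal_mean_c_int": 0.39947937687483914,
  "tumor_mean_fkc": 0.371240027257647,
  "survival_fraction": 0.6287599727423531,
  "mass_balance_relative_error": 2.891072466971935e-15,
  "perfusion_iterations": 15
}
```

Reading it: tumor IFP is elevated to 10.3 mmHg against 2.5 mmHg in normal
tissue (the classic delivery barrier); after 96 h the tumor has internalized
0.71 mol/m³ of drug against 0.40 in normal tissue, killing 37% of tumor
cells this cycle; the drug-equivalent mass balance closes to round-off.

The same scenarios are scriptable from the shell:

```sh
tumordds nanoprops --out props.csv            # wall coefficients vs NP size
tumordds netgen --seed 1 --out network.csv    # synthetic capillary network
tumordds flow --out flow.json                 # coupled perfusion summary
tumordds simulate --stage 2 --out summary.json
tumordds course --stage 3 --cycles 5 --out ledger.csv
tumordds sweep --rates 2.1e-6,1e-4,1e-3 --diameters-nm 20,100 --out sweep.csv
```

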