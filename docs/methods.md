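# Methods

`tumordds` simulates drug delivery to a vascularized solid tumor in two
spatial dimensions, from the capillary network down to internalized drug and
multi-cycle treatment outcome. This note records the model, its numerical
treatment, the choices made where the design was genuinely open, and what the
synthetic test bed does and does not establish about real tumors.

## Model overview

The pipeline is: geometry → perfusion → drug transport → pharmacodynamics.

**Geometry.** The domain is a rectangle of normal tissue (default 2 mm × 2 mm)
holding a central circular tumor (default radius 0.5 mm), discretized on a
structured cell-centered grid (default 64×64). The capillary bed is a
node/segment graph, either imported from a segmented binary vessel mask
(skeletonization → branch vectorization) or produced by the synthetic
generator: two parent vessels run along opposite domain edges — the left one
carrying the two inlet nodes at 25 mmHg, the right one a single outlet at
10 mmHg — and seeded random-walk sprouts grow from trunk points toward the
tumor with a tumor-directed drift, anastomosing across the midline. The
resulting tumor interior is more densely vascularized than the surrounding
tissue, emulating the high microvascular density of an angiogenic tumor.
Because the model is two-dimensional, per-volume quantities (the vascular
surface density S/V) are defined on a pseudo-3D slab of fixed thickness
20 µm; the thickness is a physical constant, not a grid quantity, so refining
the mesh leaves total transvascular exchange invariant.

**Perfusion.** Segment blood flow is Poiseuille flow, Q = πr⁴ΔP/(8μl), with a
distributed Starling leak L_p·2πrl·(P̄_b − P_i − σ_s(π_B − π_i)) split to the
end nodes; interior nodes balance the two. The interstitium is a Darcy medium,
v_i = −κ∇P_i, with the continuity source/sink

    −κ∇²P_i = L_p(S/V)(P_B − P_i − σ_s(π_B−π_i)) − L_pL(S/V)_L(P_i − P_L),

solved by conservative finite volumes with harmonic-mean coefficients at
tissue interfaces and a Dirichlet far-field gauge (0 mmHg) on the outer
boundary; the tumor/normal interface needs no explicit condition. Tumor
tissue has no lymphatics and an ~8× leakier wall (literature values), which
produces the elevated tumor interstitial fluid pressure plateau
characteristic of solid tumors (≈10 mmHg mean on the baseline network vs
≈2.5 mmHg in normal tissue). Network and tissue exchange P_B (length-weighted
segment pressures mapped to cells) and the local P_i under each segment, and
are iterated to a fixed point with under-relaxation 0.5 to a tolerance of
10⁻³ mmHg (≤200 iterations; both operators are factorized once and reused).

**Drug transport.** Up to five compartments per cell (mol/m³): primary
carrier C_N1, secondary carrier C_N2, free drug C_F, cell-bound drug C_B,
internalized drug C_INT. Mobile species (carriers, free drug) advect with the
interstitial fluid (first-order upwind, monotone), diffuse with
tissue-dependent coefficients, and drain into lymphatics in normal tissue;
bound and internalized drug are immobile. Free drug binds at (1/φ)K_ON·C_rec,
unbinds at K_OFF and is internalized at K_INT. Carriers release payload as a
first-order cascade (α secondaries per primary, β drug molecules per
secondary). Only the systemically injected species exchanges with the
vasculature, via the Patlak flux

    Φ_B = ϕ_B(1−σ_f)C_p + P(S/V)(C_p − C_f)·Pe/(e^Pe − 1),
    Pe = ϕ_B(1−σ_f)/(P·S/V),

with the plasma bolus C_p = C₀·exp(−t/k_d). The Peclet factor is evaluated
with a series for |Pe| < 10⁻⁶ and asymptotic limits elsewhere, making the
flux a total function including fluid reabsorption (ϕ_B < 0). The outer
concentration boundary is open: zero diffusive flux, advective outflow only.

For nanoparticles the wall coefficients P and σ_f are not tabulated but
computed from hindered transport through cylindrical wall pores
(Bungay–Brenner): λ = r_s/r_o, F = (1−λ)², H = 6πF/K_t,
W = F(2−F)K_s/(2K_t), σ_f = 1−W, P = γHD₀/L, with D₀ the Stokes–Einstein
free-solution diffusivity at 310 K and K_t, K_s the composite resistance
expansions. The trailing sum of the K expansion is implemented as
Σ c_{n+3}λⁿ (n = 0…4); this is the only reading under which H(0) = W(0) = 1,
the physically required free-solution limit (both are reproduced to 10⁻⁶).
Electrostatic particle–pore interactions are neglected. Particles at or above
the pore size can be treated as excluded (σ_f = 1, P = 0) for size sweeps.

**Pharmacodynamics.** Internalized exposure maps to kill by the empirical
doxorubicin law FKC = 1 − exp(−ω·C_INT), ω = 0.6603 m³/mol. The tumor
surviving fraction S_F is the area-weighted tumor mean of 1 − FKC; between
treatment cycles the cell count regrows by Gompertz's law toward
N_∞ = 3.1×10¹² at b = 0.0283 month⁻¹ (N₀ = 5×10⁹), and the tumor radius is
rescaled by the 2D area rule R ∝ √N while the vascular network is held
fixed. Healthy tissue is tracked with the same kill law at rate b/2; its
carrying capacity is taken as its initial count 4.64×10¹² (regrowth toward
normal), and the stored healthy/tumor density ratio 0.2 is used only for
reporting, not geometry.

## Units, parameters, dosing

All computation is in SI (Pa, m, s, mol/m³; Gompertz rates per month since
schedules are monthly). Published values in mmHg, cm, minutes and molar are
converted exactly once at load (1 mmHg = 133.322 Pa; 1 M = 1000 mol/m³).
The plasma half-life entries (6 min free drug, 1320 min nanocarriers) are
used directly as exponential e-folding times, matching the exp(−t/k_d) form
in which they appear. Two constants the literature set omits are defaulted
and configurable: blood viscosity 3×10⁻³ Pa·s and capillary radius 5 µm
(parents 7.5 µm). Interstitial nanoparticle diffusivity is published only
for the 20 nm baseline (7×10⁻¹² m²/s); other sizes scale it by Stokes–
Einstein 1/size. The secondary payload count β defaults to α = 20.

The injected dose C₀ is not published. It is treated as a configuration
parameter with an optional calibration: because the transport system is
linear in C₀, one stage-1 run at unit dose yields the exposure field per
unit dose, and C₀ is solved (bracketed root find) so the first
conventional-chemotherapy cycle kills 36.78% of tumor cells — the reported
first-cycle operating point. Stages 2/3 inject the same drug-equivalent dose
(carrier concentration C₀/α or C₀/(αβ)). The per-cycle exposure window
defaults to 96 h with FKC evaluated at the end time (C_INT is
non-decreasing, so this is its supremum).

The three-stage baseline scenario is a 20 nm primary releasing 5 nm
secondaries with fast secondary release (K_rel1 = 10⁻³ s⁻¹) and slow drug
release (K_rel2 = 2.1×10⁻⁶ s⁻¹), the regime recommended for high binding
affinity; the two-stage baseline is the 20 nm / 200 nm-pore configuration
at K_rel = 2.1×10⁻⁶ s⁻¹.

## Numerics

The semi-discrete transport system is linear, dC/dt = A·C + s₀C_p(t), with
non-negative off-diagonal entries; backward Euler therefore inverts an
M-matrix and preserves positivity without clipping. Steps follow a
geometrically growing schedule (initial 0.25 s, doubling every 48 steps),
resolving the bolus early and the slow release tail cheaply; one sparse LU
per distinct step size is cached. Halving every step changes tumor-mean
C_INT by <0.5% at the defaults (first-order convergence verified over three
refinement levels). A per-step audit recomputes transvascular influx/efflux,
lymphatic drainage and boundary outflow from the concentration fields in
drug equivalents (αβ per primary, β per secondary); the balance closes to
round-off (~10⁻¹³ %), so the 0.1% conservation contract checks assembly
consistency, not a tuned tolerance. Very stiff releases (K_rel up to
10³ s⁻¹) are handled by L-stability; in that limit the three-stage system
collapses onto the equivalent two-stage system within <1%.

Fixed problem sizes used by the checks: the interstitial-pressure oracles
run at 200×200 (plateau) and 400 cells (1D slab, matched to the analytic
cosh profile within 0.5%); conservation at 128×128 over 24 h; delivery
comparisons and treatment courses at the 64×64 default over 96 h per cycle.
Tumor-mean IFP changes by <2% when the grid is doubled from 48 to 96.

## What the synthetic baseline shows — and does not

The generator reproduces the qualitative setting: a perfused, densely
vascularized tumor fed by two inlets and drained by one outlet, elevated
tumor IFP with the peak interstitial velocity at the tumor rim, and
preferential tumor accumulation of systemic drug. It does not emulate a real
segmented image: vessel radii are uniform, there is no arterio-venous
hierarchy, no flow-adapted radii, and no necrotic core. Passing tests
establish the correctness of the discretizations and the stated qualitative
physics on this geometry, not quantitative agreement with any particular
animal model.

Two published qualitative orderings do **not** emerge from these equations
at the published parameters, and the package reports them as computed:

1. *Slow vs fast release (two-stage).* The transport chain is linear and
   time-invariant, and no mechanism penalizes early release: drug released
   in tissue cannot re-enter the vasculature (the transvascular term applies
   only to the injected species), so releasing earlier strictly increases
   internalized drug by the end of any exposure window. Faster release
   therefore always wins here (FKC 0.97 vs 0.09 at 10⁻³ vs 2.1×10⁻⁶ s⁻¹).
2. *Three-stage > two-stage > one-stage.* Extravasated carriers are mobile
   and ride the filtrate back out of the tumor; their tumor residence time
   is the fluid turnover 1/ϕ_B (≈2 h), so at the slow baseline release only
   ~1–2% of delivered payload is freed in situ and carrier-based delivery
   underperforms free drug (first-cycle FKC ≈ 0.09 vs 0.37 at equal
   drug-equivalent dose).

Both hinge on carrier retention in tissue. The parameter tables list
binding/uptake constants for the nanoparticles (φ = 0.05, K_ON, K_OFF,
K_INT), which would immobilize extravasated carriers within seconds if a
carrier-binding reaction were part of the compartment model — but the
printed transport equations contain no such term, and this package
implements the equations as printed. An optional switch
(`free_drug_vascular_exchange`) adds vessel-wall washback of released free
drug for sensitivity studies; it is off by default for the same reason.

## Known limitations

- 2D with a fixed-thickness slab; no out-of-plane transport.
- Newtonian blood, radius-independent viscosity, rigid vessels.
- No receptor saturation or depletion; binding is first-order in C_F.
- Vascular geometry is static across treatment cycles (only the tumor
  contour shrinks); no vascular normalization or regression.
- The mask-import path is a generic skeleton reconstruction; radii are
  uniform defaults, and the original image-processing pipeline of any
  specific study is not reproduced.
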