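# Methods

## Model

Thermoembolization is modeled as reactive two-phase flow in a rigid porous
medium coupled to a single-temperature bioheat equation. The constituents
are the tissue matrix (volume fraction 1 − φ), resident blood and the
injected DCACl/oil bolus, the last two sharing the pore space with
saturations summing to one. Assumptions:

- both pore fluids are incompressible and follow Darcy's law with linear
  relative permeability, λ_ı = s_ı κ_ı / μ_ı;
- capillary pressure follows a Brooks–Corey law with pore-size index 1,
  p_c = p_bolus − p_blood = p_d / s_blood, regularized by a saturation
  floor s_min = 1e-3 that caps p_c at p_d/s_min as blood is fully
  displaced (the raw law is singular there);
- DCACl escapes the oil and hydrolyzes with first-order kinetics at rate
  γ; hydrolysis converts bolus mass to blood mass at volumetric rate
  γ ρ_DCACl ϵ φ s_bolus and releases h = h_DCA + h_salt per mole
  (hydrolysis and instantaneous secondary neutralization heats are
  additive);
- tissue, blood and bolus are in local thermal equilibrium, so one mixture
  temperature is transported with volume-fraction-averaged conductivity
  and heat capacity; temperatures are handled in °C throughout (the model
  is linear in u, so the offset to kelvin cancels);
- blood perfusion heat sink, coagulation/vessel-spasm embolic feedback,
  temperature-dependent properties and thermal damage models are outside
  the model.

One structural property of this formulation is worth stating explicitly:
the bolus-phase mass sink is the DCACl consumption rate
γ ρ_DCACl ϵ φ s, so the saturation decays with effective rate
γ_eff = γ ϵ ρ_DCACl / ρ_bolus (≈ 0.23 γ at the default loading), while
the heat source burns at γ s. Integrated to completion, the released heat
is therefore ρ_bolus/(ϵ ρ_DCACl) times the initial DCACl enthalpy, and a
first-order fit to a well-mixed temperature rise recovers γ_eff, not γ.
The package implements the equations as formulated; the global
initial-enthalpy audit closes exactly when the bolus is pure DCACl
(ϵ = 1, ρ_bolus = ρ_DCACl), which is how the corresponding test is
parameterized.

## Parameters

Defaults describe a 2 mol/L DCACl-in-oil bolus injected into soft tissue
at ambient 21 °C; all SI except temperature (°C).

| parameter | default | unit | note |
|---|---|---|---|
| φ porosity | 0.05 | – | soft-rock analogue for tissue |
| ϵ DCACl fraction of bolus | 0.1919 | – | from 2 mol/L, W = 0.147 kg/mol, ρ = 1532 kg/m³ |
| γ hydrolysis rate | 2.33e-3 | 1/s | fitted from first-order temperature rise |
| h_DCA / h_salt / h | 93e3 / 45e3 / 138e3 | J/mol | h_salt = h − h_DCA by additivity |
| ρ, c, k (blood) | 1045, 3600, 0.53 | kg/m³, J/kg/K, W/m/K | |
| ρ, c, k (bolus) | 1280, 1970, 0.15 | | oil-dominated mixture |
| ρ, c, k (tissue) | 1050, 3600, 0.5 | | k and ρ are literature-typical soft-tissue values (only c is tabulated for tissue); configurable |
| μ blood / bolus | 8.9e-4 / 7.0e-4 | Pa·s | |
| κ (both phases) | 5e-12 | m² | |
| p_d displacement pressure | 0.074 atm | Pa | |
| p_injection / p₀ | 1.16 / 1.0 atm | Pa | delivery overpressure 0.16 atm |
| u_init / u₀ | 21 / 97.7 | °C | u₀ calorimetric: 2 mmol DCACl in 1 g tissue |
| s₀ inflow saturation | 1 | – | bolus enters as the only constituent |
| delivery window | 25 | s | |
| horizon / frame interval | 1200 / 22.3 | s | 20 min monitoring, one thermometry frame per 22.3 s |

The Robin coefficient α of the vessel-interface temperature condition
−α ∇u·n = (u₀ − u)(φ Σv)·n has no published value; by default it is
evaluated per face as k_face/(ρ_blood c_blood |v|), which drives the face
temperature to u₀ in the advection-dominated limit. A fixed α can be set
in the configuration. This default is a modeling choice of this package.

## Discretization

Cell-centered finite volumes on uniform structured grids (1-D/2-D/3-D)
with two-point flux approximation, backward-Euler time stepping, and
operator splitting per step: pressure solve → flux reconstruction →
implicit saturation transport → implicit temperature transport (the
temperature step uses end-of-step saturations, introducing an O(dt)
splitting error consistent with backward Euler).

**Pressure.** Harmonic-mean total face mobility; the capillary term
∇·(λ_bolus ∇p_c) is evaluated at the current saturation on the right-hand
side, with zero capillary gradient across boundary faces (the far boundary
prescribes ∇s = 0; at the vessel the capped p_c of a pure bolus would be a
regularization artifact). Vessel faces are Dirichlet at the injection
pressure during delivery, far faces Dirichlet atmospheric; a sealed box
(pure Neumann) pins one cell to p₀ as gauge.

**Saturation.** The bolus flux −λ_o ∇(p_blood + p_c) is advanced in
fractional-flow form: f_o(s) v_T − D(s) ∇s, where v_T is the total face
flux taken *discretely consistent with the assembled pressure equation*
(so cellwise flux divergence matches the reaction volume source),
f_o = λ_o/(λ_o + λ_b) is upwinded by the sign of v_T and treated
implicitly by Newton iteration (absolute tolerance 1e-10 scaled, relative
1e-8, 25 iterations, backtracking line search), and
D = (λ_o λ_b/λ_T)·dp_c/ds is the capillary diffusivity, lagged at the old
saturation, harmonic-averaged at faces, zero beyond the regularization
floor. This form was chosen over direct upwinding of the phase velocity
because only the total flux is discretely divergence-consistent: with raw
phase velocities, stagnation cells can accumulate saturation without
bound, while the fractional-flow upwind scheme is an M-matrix and keeps
s ∈ [0, 1] for any time step. Zero-velocity faces take the arithmetic
mean of the adjacent saturations (the flux is zero there regardless).
Inflow faces carry the inflow composition: pure bolus (s₀) at the vessel,
pure blood at the far boundary. The hydrolysis sink is implicit.

**Temperature.** Diffusion by two-point flux with harmonic-mean mixture
conductivity; convection in non-conservative form with first-order
upwinding (only inflow faces contribute, bringing the upstream
temperature), which together with the implicit treatment yields a
monotone scheme with a discrete maximum principle. The vessel inflow
condition is closed by solving the Robin relation for the face
temperature, u_face = ω u₀ + (1 − ω) u_cell with
ω = |q_n| / (α/d + |q_n|), and applying both the advective and the
half-cell conductive flux at u_face. Far faces are zero-gradient;
advective outflow leaves at the cell temperature.

**Delivery stasis.** When the injection window closes, all convective and
capillary transport stops and velocities are identically zero — the
delivered bolus is trapped and only diffusion plus the delayed reaction
continue. This mirrors the physical observation that the injection fills
the vascular bed and flow stagnates; a configuration option
(`post_injection: p0`) instead keeps solving the flow with the vessel
held at atmospheric pressure.

**Linear solves.** Jacobi-preconditioned BiCGStab to relative residual
1e-10 with the previous field as initial guess, falling back to sparse LU;
a failing implicit step is retried at dt/2 down to dt_min = 1e-3 s.

Default dt = 1 s resolves both the 25 s delivery and the reaction time
scale (1/γ ≈ 430 s); checkpoints default to the 22.3 s thermometry frame
interval. The bundled reference scenario uses a 4 cm cube at 16³ cells
with a single-face vessel; at the default pressure and permeability the
25 s delivery injects ≈ 4.5 mL against a 3.2 mL pore volume, i.e. the
bolus perfuses the whole synthetic vascular bed, with saturation and
temperature decaying monotonically away from the vessel.

## Synthetic data

Two generators stand in for experiment-derived inputs:

- **Geometry**: an axis-aligned box with a vessel represented purely as
  tagged inflow faces (a tube of given radius around a centerline
  polyline). This replaces image-segmented anatomy; it reproduces the
  topology of "bolus enters through a vessel interface into porous
  parenchyma" but none of the branching vascular geometry, so simulated
  temperature *maps* are not comparable to organ-scale measurements —
  only transport properties and qualitative behavior are.
- **Thermometry**: noisy frames sampled from a simulated trajectory every
  22.3 s with i.i.d. Gaussian noise of standard deviation σ_ref/SNR
  (σ_ref = 40 °C·SNR-units, default SNR 40 → σ = 1 °C, typical of PRF
  temperature maps at moderate SNR). Real thermometry noise is spatially
  correlated and signal-dependent; the generator emulates only its
  first-order Gaussian statistics, so passing comparison tests shows the
  analytics pipeline is self-consistent, not that the model matches a
  scanner.

## Verification

The test suite checks the discrete solvers against independent references:
exact linear pressure profiles and hand-computed Darcy fluxes in 1-D; a
dense direct solve of the assembled pressure system; the closed-form
saturation decay s(t) = s(0) e^(−γ_eff t) and the well-mixed heating ODE
(both < 0.5%); the 1-D heat kernel (< 0.1 °C on 200 cells); an explicit
tiny-dt upwind reference for the implicit saturation advection (integral
L1 < 1e-3 on 100 cells); exact mass conservation in a sealed box; a
cross-module energy audit (reacted moles × h vs. stored ρcΔu, < 1%); and
first-order step-halving consistency of the coupled loop. Runs are
deterministic given the configuration and seed.

## Limitations

- First-order accuracy in space and time; upwind numerical diffusion
  smears saturation and thermal fronts.
- Operator splitting freezes the flow within a step; very large dt during
  the delivery window trades accuracy for stability (the scheme remains
  bounded).
- The energy ledger is a strict audit only for insulated runs; during
  delivery the non-conservative convection discretization does not tally
  boundary heat advection exactly.
- The heat budget of the underlying model overcounts total releasable
  enthalpy for ϵ < 1 (see Model); results over the 20 min horizon are
  dominated by the early part of the decay where the effect is modest,
  but completion-time energy totals should be interpreted with care.
- No perfusion heat sink, no embolic flow feedback, no damage model; the
  vessel lumen is not resolved.
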