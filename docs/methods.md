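# Methods

## The model

`cuticle_uptake` simulates foliar uptake of a hydrophilic ionic active
ingredient (AI; CaCl2 in the bundled preset) from sessile droplets
applied to an isolated, astomatous plant cuticle, with a well-stirred
water bath behind the membrane acting as receiver. Ionic solutes cannot
use the lipophilic route; they cross the cuticle through nanometre-scale
aqueous pores that form and swell as water sorbs to the polar cutin
polymers. The model is quasi-one-dimensional in the membrane depth
x ∈ [0, b] and couples two fields, the pore concentrations of AI and of
free water:

    ∂t(ε c_AI)  = ∂x [ D_AI  ∂x(ε c_AI) ]
    ∂t(ε c_H2O) = ∂x [ D_H2O ∂x(ε c_H2O) ] − (2/r_p)(1 − ε) ∂t Γ_H2O

Everything nonlinear enters through the microstructure closure chain,
evaluated pointwise from the local free-water concentration c = c_H2O:

1. **Langmuir monolayer adsorption.** Γ(c) = Γ_S βc/(1 + βc) is the
   surface concentration of water bound to the pore wall (mol/m²).
2. **Steiner-chain pore radius.** The adsorbed molecules form a closed
   ring of n = Γ·π·r_H2O²·N_A tangent spheres lining the pore;
   r_p = r_H2O [1 + 1/sin(1/(Γ r_H2O² N_A))]. The construction needs
   n ≥ 3; below that the monolayer picture is meaningless and the code
   raises rather than extrapolates.
3. **Porosity.** Pores are evenly spaced, ρ0 per m²; each owns a control
   area A_Π = (L/(√n0 + 1))² with n0 = ρ0 L², so
   ε = π [r_p(√n0 + 1)/L]². ε ≥ 1 (overlapping pores) is a hard
   model-validity error, never clamped — clamping would silently break
   the mass balance.
4. **Fractal-tortuosity diffusivity.** D_i = D_i^bulk · ε^F̄ with
   F̄ = F_s/(2 − F_s), 1 < F_s < 2. Larger F_s means more tortuous,
   lamellate pores and sharply lower transport.

Saturation closes the calibration: Γ_S is defined by inverting the
radius law at r_p = r_p^max, and β is fixed by requiring that pure water
in the pore reproduce the humidity-set initial radius r_p^max·H. Both
printed constants of the preset (Γ_S = 9.6832e−4 mol/m², β = 3.77e−5
m³/mol) emerge from this chain rather than being stored.

### Boundaries

*Drop side (x = 0).* The applied drop is a spherical cap pinned at
contact radius r_drop = (3V0/(π g(θ0)))^{1/3} sin θ0,
g(θ) = (1 − cos θ)²(2 + cos θ). Its AI content obeys

    d(V c0)/dt = −k c0 + ρ0 A_drop A_Π D_AI(0) ∂x(ε c_AI)|_0

with c_AI(0, t) = c0 continuous into the pore mouths, a first-order
irreversible ion-binding sink k c0 on the cuticle surface, and the pore
coupling group ρ0 A_drop A_Π counting the pores under the drop. The
drop's water concentration follows volume conservation,
c_H2O(0, t) = (1 − v̄_AI c0)/v̄_H2O.

*Evaporation.* Diffusion-limited evaporation into still air at relative
humidity H removes water at the constant-contact-radius closed-form rate

    V(t) = V0 − 2 δ D_evap ψ r_drop t / ρ_L ,   ψ = M_w P_v (1 − H)/(R T),

clamped at the solubility floor V_∞ = c_AI0 V0 / c_sat: the salt is
deliquescent, so the residue persists as a saturated liquid film instead
of drying out, and the drop concentration can never exceed c_sat. The
published form of this law is typographically damaged; the implemented
reconstruction is pinned by four checks (V(0) = V0 exactly; strict
decrease for ψ > 0; dependence only on the grouped driving term
2 D_evap ψ t/(r_drop² ρ_L); floor time within a factor 3 of the
quasi-steady estimate V0 ρ_L/(2 r_drop D_evap ψ)), by the observation
that 2δ ≈ 3.99 is numerically the flat-disk vapor capacitance of the
cited sessile-drop derivations, and by reproducing the narrative of the
reference experiment (the 10 g/L drop reaches ≈5,000 mol/m³ at 1 h). A
frozen regression fixture in the test suite detects any future edit.

*Bath side (x = b).* Perfect sink for AI (c_AI = 0) and pure-water
reservoir (c_H2O = c_H2O^pure = ρ_L/M_w).

Note one inconsistency carried over from the source constants: the
volume-conservation closure gives 1/v̄_H2O = 55 411.15 mol/m³ for a pure
drop while the bath value is ρ_L/M_w = 55 409.78 mol/m³ (2.5e−5
relative). Both printed values are kept; the mismatch only produces a
negligible residual at the surface node.

### Initial state

Rehydrated cuticle: no AI in the pores, pure water throughout,
r_p(x, 0) = r_p^max·H everywhere (made consistent with pure water by the
β calibration above), the drop at its applied concentration — which
slightly depresses the surface water node via volume conservation.

## Numerics

Method of lines on a uniform vertex-centred mesh: second-order central
differences with face-averaged diffusivities (arithmetic mean by
default, harmonic available via `NumericsConfig.face_average`), and
second-order one-sided gradients for the drop coupling and the bath
flux. The state-dependent accumulation term ∂t(εc) is expanded with
exact analytic chain-rule factors (dΓ/dc, dr_p/dΓ, dε/dr_p are all
closed-form), giving an explicit-in-ẏ ODE system solved with scipy's
implicit BDF method and a sparse Jacobian pattern. The state vector is
the interior nodal concentrations plus three scalar ledgers: the drop
content u = V·c0 and the cumulative bound and bath-outflow moles.
Carrying the outflow as a state makes the reported uptake
M_t = 10⁶ M_w,AI n_drops × (bath moles) independent of the report-grid
density; the bath flux itself spikes near the floor time, where
trapezoidal quadrature of a sparse flux series would misestimate uptake
by several percent (the trapezoidal series operation is still provided
as `cumulative_uptake` and agrees on dense grids).

Integration is split at the floor time t* (a closed-form root of the
volume law), so the stiff integrator never steps across the non-smooth
volume clamp. Defaults: 101 nodes, rtol 1e−8, scaled atol 1e−10, 500
report points (log-informed early coverage densified around t*). With
these settings a 48-h preset run takes under a second on one CPU; the
48-h percent uptake is grid-converged to ~1e−5 relative at 101 nodes,
with successive-difference ratios approaching the second-order value 4
from below (≈2.8–3.5 over 51→401 nodes; a subdominant boundary term
decays more slowly). The four-way AI mass audit
(drop + cuticle + bound + bath vs applied) closes to ~1e−5 relative at
every report time, well inside the 0.1% tolerance asserted in the
tests. Nothing in the package uses randomness; fixed configurations
reproduce bit-identically.

## Outputs and analyses

`simulate` returns field snapshots, drop volume/concentration, bath
flux, cumulative mass M_t (µg), percent uptake (M_t over the applied
mass, ×100) and the audit ledger. On the bundled preset (tomato fruit
cuticle, five 1-µL CaCl2 drops at 10 g/L, 70% humidity, 20 °C) the
48-h percent uptake is ≈39.8%, with ≈60% of the applied ions lost to
surface binding, the drop reaching its solubility floor at ≈0.77 h and
the interior returning to (c_AI = 0, c_H2O = pure) at late times.

*Sensitivity.* One-factor-at-a-time: each parameter is scaled by
1 + f (default f = ±0.1) and the ratio |Δ%uptake|/|Δ%parameter| is
reported as a percentage. Composites are perturbed without touching any
other dimensionless group: the tortuosity exponent F̄ through F_s, and
the pore-volume ratio γ̄ = ρ0 A_drop A_Π b/V0 through a scale factor
applied to the coupling group ρ0 A_drop A_Π everywhere it appears (drop
boundary condition, uptake conversion, cuticle content) — the only
perturbation of γ̄ alone that keeps the mass audit closed. Note that
under this isolation uptake *increases* with γ̄: a larger coupling
drains the drop faster relative to the fixed binding sink. On the
preset, F̄ is by far the most influential parameter and c_AI0 is nearly
irrelevant to the final percent uptake (it shifts the floor time, not
the plateau).

*Humidity sweep.* One simulation per H; uptake is monotone in H,
≈73% at H = 0.95 and nearly flat over 90–100%.

*Calibration.* The three structure parameters (F_s, k, ρ0) are fitted
to a cumulative-uptake series by bounded trust-region least squares in
(F_s, log10 k, log10 ρ0), with a fixed five-point multistart list and a
finite-difference step (1e−4 relative) chosen to sit well above the
integrator noise floor. The objective (sum of squared M_t residuals,
µg²) is declared in the result. Noise-free self-consistency recovers
the generating values essentially exactly from all five starts.
Identifiability caveat: ρ0 and F_s compensate along a sloppy valley
(transport ∝ ρ0^(1+F̄)), so a few percent of data noise moves ρ0 by
tens of percent while the fitted uptake curve, F_s and k stay tight.

## What the preset emulates — and what it does not

The preset reproduces the published isolated-cuticle experiment:
astomatous tomato fruit cuticle, droplets without surfactant, constant
temperature and humidity, a stirred receiver bath. Passing tests
therefore say nothing about stomatous leaves, surfactant-laden
formulations (beyond varying θ0), temperature-dependent properties,
crystallising salts, lateral transport, or attached leaves with phloem
export — all outside the model's scope. Constant-contact-radius
evaporation is assumed throughout; constant-contact-angle or mixed
modes are not modelled. Ion binding uses a constant rate with unlimited
surface sites. Multilayer (BET-type) water sorption is excluded by the
monolayer construction.

## Known limitations

- The evaporation closed form is a reconstruction (see above); its
  uncertainty is why the humidity acceptance band is wide.
- Sensitivity magnitudes depend on the perturbation size because the
  response is strongly nonlinear; published rankings obtained with an
  unstated perturbation may interleave differently.
- Below n_ring = 3 adsorbed molecules (very dry pores, H ≲ 0.15 in the
  preset geometry) the constitutive chain is undefined and the model
  refuses to run rather than extrapolate.
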