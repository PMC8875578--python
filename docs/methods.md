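# Methods

`magipt` simulates drug delivery to a peritoneal tumor during one hour of
intraperitoneal (IP) chemotherapy, with and without magnetic assistance:
drug-coated magnetic nanoparticles (MNPs) bathe the tumor surface and an
external permanent magnet pulls them into the tissue against the
microenvironmental barriers (elevated interstitial pressure, outward
convection, vascular washout, and binding-limited penetration).

## Model

### Interstitial fluid flow

Tumor tissue is treated as a porous medium.  Interstitial fluid velocity
and pressure obey Darcy's law and steady incompressible mass balance,

    v_i = −κ ∇P_i,        ∇·v_i = ϕ_B − ϕ_L,

with transvascular filtration from Starling's law,

    ϕ_B = L_p (S/V) (P_B − P_i − σ_s (π_B − π_i)),

and ϕ_L = 0 (solid tumors lack a functional lymphatic system).  The
necrotic core (r < R_n) has no functional vessels: ϕ_B is switched off
there while the hydraulic conductivity κ is unchanged, and pressure and
flux are continuous across the interface.  The rim carries a Dirichlet
condition P_i = 0 (peritoneal fluid as the pressure gauge).

Because ϕ_B is linear in P_i this is a single sparse linear solve.  The
governing dimensionless group α = R·√(L_p(S/V)/κ) ≈ 37 means pressure sits
at the Starling equilibrium P_e = P_B − σ_s(π_B − π_i) = 1470 Pa in the
bulk and drops to zero across a boundary layer of width R/α ≈ 0.27 mm —
which is also where all the interstitial velocity lives (peak
κ·P_e·√(L_p(S/V)/κ) ≈ 0.16 μm/s, outward).  This outward rim convection is
the classic barrier to IP drug penetration.

### Magnetostatics and the particle force

The magnet is a rectangular bar (cross-section l × h = 20 × 10 cm),
uniformly magnetized toward the tumor with remanence B_rem, its face a
distance d from the tumor center on the +y axis.  Outside the body the
field equals that of two equivalent surface-current sheets and has a
closed form (arctan/log) with an analytic Jacobian, so no magnetostatic
mesh solve is needed; the magnet body's permeability is absorbed by the
equivalent-current representation.  The force on a particle of radius a is

    F_m = ½ V μ₀ χ_eff ∇|H|²,      χ_eff = χ/(1 + χ/3),  V = (4/3)πa³,

clamped when the induced moment χ_eff|H| reaches the saturation
magnetization (μ₀M_sat = 0.5 T by default) by replacing the |H| factor
with M_sat — saturation caps the magnitude, never the direction.  Balancing
against Stokes drag gives the magnetophoretic velocity v_e = F_m/(6πaη).

Distance convention: `distance_d` runs from the tumor center to the
nearest magnet face.  With the magnet above, the force inside the tumor
points up, so drug enters through the bottom face of the tumor and the
penetration half-depth for magnetic scenarios is measured along the
vertical diameter starting at the bottom rim.

### Drug transport

Free drug moves by convection (v = v_i + v_e), diffusion, transvascular
loss, and reversible binding with internalization:

    ∂C_F/∂t = −v·∇C_F + D_mnp ∇²C_F − (1/φ) K_ON C_rec C_F + K_OFF C_B + Φ
    ∂C_B/∂t = (1/φ) K_ON C_rec C_F − (K_OFF + K_INT) C_B
    ∂C_I/∂t = K_INT C_B

Transvascular exchange uses the pore model,
Φ = ϕ_B(1−σ_f)C_p + P(S/V)(C_p − C_F)·Pe/(e^Pe − 1) with
Pe = ϕ_B(1−σ_f)/(P·S/V), evaluated with a series expansion for |Pe| <
1e−6.  Drug is dosed intraperitoneally, so the plasma is a sink: C_p = 0
and Φ reduces to a volumetric washout −P(S/V)·f(Pe)·C_F
(P·S/V = 0.06 s⁻¹ with the default parameters — a 17 s residence time
that confines conventional delivery to a ~60 μm rim layer,
w½ ≈ √(D/(P·S/V))·ln2).  The necrotic core exchanges nothing with blood;
binding remains active there.  The rim carries a Dirichlet condition
C_F = C_outer, constant over the treatment hour (continuous instillation).

### Size dependence

The tabulated effective diffusivity D_eff = 3.4e−10 m²/s refers to the
100 nm reference particle.  Other sizes use

    D(a) = D_eff · (a_ref/a) · exp(−(a − a_ref)/ℓ),   a_ref = 100 nm,

a Stokes–Einstein 1/a factor times an exponential extracellular-matrix
(ECM) hindrance with length scale ℓ.  The same hydrodynamic hindrance
factor multiplies the magnetophoretic mobility inside tissue (generalized
Stokes–Einstein: diffusivity and mobility are both k_BT × mobility-limited),
so v_e in tissue carries exp(−(a−a_ref)/ℓ) as well.  This single mechanism
produces the experimentally familiar interior optimum in particle size:
magnetic force grows as a³ (so v_e ∝ a² before hindrance) while mobility
collapses exponentially beyond the ECM pore scale.  The default
ℓ = 150 nm places the maximum of a²·exp(−(a−a_ref)/ℓ) at a = 300 nm, the
optimum reported for magnetically assisted IP delivery; it is a closed-form
choice, not a fit.

### Cell kill and efficacy metrics

Cell survival follows an exponential in-vitro dose–response on
internalized drug, SF = exp(−10⁶·ω·C_I) with C_I in molar units and
ω = 0.4938 m³/mol (equivalently exp(−10³·ω·C_I) for C_I in mol/m³; the
molar reading is the only one consistent with the published kill
fractions at the published tissue concentrations).  Metrics:

* **w½** — depth from the border at which C_F first falls to half the
  border value (first crossing, linear interpolation; a profile that
  never crosses is flagged as full-ray penetration),
* **PA_rel** — % of tumor area with C_F above 0.5% of the border value
  (threshold configurable; 0.5% makes the conventional annulus depth
  ln(200)·w½/ln2 ≈ 0.46 mm, matching the reference conventional area),
* **FK_PA** — area-mean kill fraction inside the penetration area,
* **FK_eff = FK_PA·PA_rel/100** — whole-tumor effective kill (an exact
  identity in this package, at every scenario).

## Discretization

Finite volumes on a polar grid over the tumor disk.  Radial spacing is
graded: 8 μm at the rim (≥6 cells across the 60 μm conventional
boundary layer) coarsening geometrically (ratio 1.12) to 150 μm inside;
96 uniform angular cells with centers on the vertical diameter.  Default
grid ≈ 85 × 96 cells.

Convection is first-order upwind; diffusion uses two-point face fluxes.
The conservative flux divergence is supplemented with a +C(∇·v) source so
the discrete equation matches the advective transport form exactly while
face fluxes remain available for exact mass bookkeeping (∇·v is the
discrete face divergence; for the interstitial part it equals ϕ_B).  Time
stepping is backward Euler (θ = 1 default, θ-weightable for the transport
operator) with Δt = 2 s over 3600 s; the binding pair (C_F, C_B) is
coupled implicitly by eliminating C_B, so the system matrix is constant
and factorized once (sparse LU).  The matrix is an M-matrix: all three
fields stay non-negative, C_I is non-decreasing cell-wise, and the
discrete binding exchange conserves C_F + C_B + C_I exactly.  The flow
solve, an elliptic problem, uses a sparse direct solve with no time
marching; the flow and force fields are frozen before transport begins.

Degenerate inputs: B_rem = 0 short-circuits the magnetic terms and
reproduces the conventional pipeline bit-for-bit; C_outer = 0 keeps the
zero state exactly; an empty penetration area reports zero kill metrics.

## Calibrations

Two published anchors consume two scalars; everything else is a
prediction.

1. **Rim concentration** — the instilled concentration at the tumor
   border is not measured; the transport system is linear in it, so a
   single unit run fixes C_outer from the conventional 60-min tumor-mean
   free-drug anchor (0.0013 mol/m³ → C_outer = 0.088 mol/m³).
2. **Magnetophoretic mobility scale** — parameter tables for MNP delivery
   rarely pin down the particle's magnetic content (susceptibility,
   saturation moment, number of magnetic cores per drug carrier).  A bare
   susceptibility cannot serve as the calibration knob: χ/(1+χ/3) is
   bounded by 3 and the 0.5 T saturation clamp bounds the force at
   ~4e−15 N for a 100 nm particle in this geometry, giving v_e ≤ 2e−6 m/s
   — while the anchor half-depth w½ = 0.08 cm requires v_e ≈ 7.5e−5 m/s
   against the 0.06 s⁻¹ washout.  The package therefore calibrates one
   dimensionless scale multiplying the force magnitude (direction, B_rem²
   scaling, a³ scaling, and spatial shape untouched), by monotone
   bisection on the baseline scenario's w½.  The calibrated value
   (≈ 122 for the shipped baseline) is recorded in run provenance.

## What the model does and does not capture

The simulator reproduces, with the two calibrations above, the reference
flow field (peak pressure at the Starling equilibrium, rim velocity
0.16 μm/s), the conventional penetration metrics, and — notably — the
relative penetration half-depths of every magnetic sweep (particle size,
magnet strength, magnet distance) to within ~±25%, including the
quadratic growth with B_rem and the size optimum at 300 nm.

Two structural consequences of the governing equations deserve emphasis
because they bound what any calibration can achieve:

* **Area metrics flood for deep penetration.**  Past the entrance region
  the steady C_F profile decays exponentially with a single length
  L = w½/ln2, so the area threshold at 0.5% of the border value is
  crossed at depth ln(200)·L ≈ 7.6·w½.  Anchoring w½ = 0.08 cm therefore
  necessarily floods most of the disk above threshold (PA_rel ≈ 70%),
  and the reported effective-kill fractions for magnetic scenarios are
  correspondingly high.  Published table sets whose penetration areas
  correspond to ≈1×w½ for magnetic cases but ≈7.6×w½ for the
  conventional case are mutually inconsistent under these equations; no
  threshold choice satisfies both.
* **A weak magnet cannot suppress net penetration.**  The angle-averaged
  penetration length is convex in the face-normal velocity (enhancement
  on the entry side outweighs suppression on the exit side, by Jensen's
  inequality), so any non-zero force increases area-mean penetration
  over the conventional case.  Reported *reductions* of penetration area
  at weak field strength are outside this model class.

Other limitations: 2D plane geometry (infinite-bar magnet, disk tumor);
no poroelasticity; no drug release from the carrier (drug and particle
are one species); no washout phase after the instillation hour; no
inter-particle dipole interactions; constant rim concentration (no
peritoneal pharmacokinetics); necrotic-core radius defaults to R/2 and is
configurable — conventional results are insensitive to it (drug never
reaches the core), deep-penetration magnetic results are not, since the
core's missing vascular washout lets drug accumulate there.

## Verification

Independent oracles (different discretization families from the main
solvers) back the test suite and the `magipt verify` subcommand: a dense
1D radial finite-difference Darcy solve (< 0.5% of the 2D solution), the
Biot–Savart quadrature over the equivalent surface currents (< 0.1% of
the closed-form field), a fine-grid explicit 1D slab integration of the
transport system (half-depth within a few % of the 2D rim profile), and
a mass-balance auditor that re-derives every flux and source of a
recorded transient from the stored states (< 1% residual; exact up to
round-off for the backward-Euler scheme).  Grid and time-step refinement
(halving all spacings and Δt) moves w½ by 0.2% (conventional) and 1%
(magnetic baseline).
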