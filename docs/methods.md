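# Methods

## Physical model

Blood in a terminal-villus capillary is treated as a steady Stokes fluid
of constant effective viscosity μ (red-blood-cell and Fahraeus–Lindqvist
effects are out of scope).  Oxygen is carried dissolved in plasma
(concentration c, diffusivity D) and bound to hemoglobin; with binding
assumed instantaneous and the fetal dissociation curve S(P_O₂)
linearized through the origin over 0–60 mmHg (slope K), the two pools
collapse into one advection–diffusion equation with the advective term
multiplied by a constant enhancement

    B = 1 + c_max·K·k_hn/ρ_bl,

where c_max is the oxygen content of saturated blood, k_hn the Henry
coefficient and ρ_bl the blood density.  The shipped defaults are the
literature-based values D = 1.7×10³ μm²/s, μ = 10⁻³ Pa·s,
c_mat = 0.07 mol/m³ (= 2.24 g/m³, molar mass 32 g/mol), B = 141 and
K = 0.019 mmHg⁻¹.  B is shipped as a constant because its constituents
are not individually needed by any formula; when all constituents are
supplied they must reproduce B to 10⁻¹² relative, and a pluggable
saturation law S(P) (a Hill-curve factory is provided) activates the
nonlinear mode, in which the local enhancement
1 + (c_max·k_hn/ρ_bl)·S′(P) is iterated to a damped fixed point
(damping 0.5, relative update < 10⁻⁸, cap 100 iterations) with S′
evaluated by central differences of the user's law via Henry's law
P = k_hn·c/ρ_bl.

Internal units are μm, s, Pa and g throughout; converters (mol/m³,
g/m³) live only at the I/O boundary.  Transfer rates are reported in
μg/s.

## Reduced-order transfer model

For a capillary of radius R₀ = sqrt(V/πL), length L, resistance R
(measured, or 8μL/πR₀⁴ by Poiseuille) and villous distance d:

* Lévêque regime (thin wall boundary layer, high Pe_eff):
  N₁ = α·c_mat·(D²·B·ΔP·L²/R)^{1/3}, α = (12π²)^{1/3}/Γ(4/3);
* equilibrated regime (outflow saturated, low Pe_eff): N₂ = c_mat·B·ΔP/R;
* diffusion-limited bound through the villous annulus:
  N_max = D·A·c_mat/(R₀·ln(1+d/R₀));
* regression across the flow-limited regimes:
  N_flow = K₁K₂ΔP/(K₂+K₁ΔP^{2/3}) with K₁ = c_mat·B/R,
  K₂ = α·c_mat·(D²BL²/R)^{1/3};
* villous correction: N = N_flow/(1+N_flow/N_max), with the capillary
  surface concentration depleted to c_inner = c_mat·(1 − N/N_max).

Branched capillaries are treated as one equivalent tube.  The Lévêque
prefactor assumes developed Poiseuille flow in a circular tube; applying
it to irregular capillaries is an order-of-magnitude approximation, not
a claim of accuracy.  The regime classifier operationalizes the
asymptotic inequalities ("much greater") with a configurable factor
(default 10; chosen as the conventional order-of-magnitude margin) and
reports boundary cases as `crossover` rather than guessing.  The total
length L enters the transfer formulas (this reproduces the reference
table's L²/R row), while the longest inflow-to-outflow path enters only
the equilibration inequality.  When an externally computed (3D
numerical) N_max is available it is preferred over the annular closed
form, which ignores the real villous topography.

## Axisymmetric finite-element model

The meridian domain 0 ≤ r ≤ R(z), 0 ≤ z ≤ L is meshed from a structured
grid (triangulated quads).  The radial grid is graded toward the wall so
the first cell is no thicker than R₀·Pe^{-1/3}/4 at the target Péclet
number (default 500), since the concentration boundary layer scales as
Pe^{-1/3}; the axial grid conforms to the dilation window and clusters
grid lines toward the window edges, where the wall concentration jumps
from insulated to oxygenated.  Default resolution: 13 radial cells,
axial spacing max(R₀/8, L/160).  At these defaults the transfer rate of
the reference dilation changes by less than 1% under one refinement
level, and the enhancement ratio (dilated over straight) changes by
less than 0.1 percentage points under a doubling of resolution.

*Flow.*  Taylor–Hood P2/P1 elements in the r-weighted axisymmetric weak
form (with the u_r/r² curvature term).  The ends carry natural
normal-stress conditions (p = ΔP at the inlet, 0 at the outlet) with
zero tangential velocity, exactly the pressure-driven formulation — so
entrance effects are part of the computed resistance; the wall is
no-slip and the axis a symmetry line.  This pair reproduces Poiseuille
flow in a straight tube to machine precision (the exact solution lies
in the discrete space).  The driven end can be swapped to the outlet,
which by Stokes linearity must reproduce the same flow rate; this is
the shipped reversibility check.

*Transport.*  P1 elements with streamline-upwind (SUPG) stabilization,
τ from the directional element length h_UGN and the upwind function
coth(Pe_h) − 1/Pe_h, active only where the element Péclet number
exceeds 1.  A discontinuity remains at the oxygenation-window edges, so
after the first solve two further passes add Codina-style residual-based
crosswind diffusion (coefficient 0.7), which suppresses the spurious
under/overshoot; with the defaults the nondimensional concentration
stays within [−10⁻³, 1+10⁻³] for the reference configurations
(Pe_eff ≲ 150).  At substantially higher Péclet numbers, or during
optimization line searches through extreme trial shapes, the hard bound
check can be run at a documented looser level (5×10⁻³); final reported
optima are re-verified at the strict default.  The oxygen boundary
conditions are c = 0 at the inlet, c = c_mat on the dilated wall
section γ_d, zero diffusive flux on the undilated wall γ_u and the
outlet.  An optional variant holds c = c_mat on a chosen fraction of
γ_u adjacent to the window, approximating additional oxygen transfer
upstream/downstream of the dilation; it is an approximation, the exact
upstream/downstream formulation being out of scope.

*Outputs.*  The transfer rate is the advective outflow
N = 2π∫ B·u_z·c·r dr over the outlet (for the nonlinear mode, the
advected total is c + c_max·S(P)).  Boundary diffusive fluxes are
recovered by the consistent residual method — summing weak-form
residuals at Dirichlet boundary nodes — which on coarse meshes is an
order of magnitude more accurate than pointwise gradient evaluation
(both are shipped, the naive one for comparison only).  The flux
balance |N_out − (wall influx − inlet loss)|/N is reported with every
solve and is ≤ 1% at the defaults.  The solve is performed for the
nondimensional field ĉ = (c − c_in)/(c_mat − c_in); dimensional fields
at any boundary concentrations follow by exact rescaling without a
re-solve (linear mode only).

## Dilation shape family

Inside a window of length λ the wall is a truncated Fourier series in
ζ = z − z_start with the four linear constraints R(0) = R(λ) = R₀,
R′(0) = R′(λ) = 0 enforced exactly by eliminating a₀, a₁, b₁, b₂ (the
low-order terms always exist for n ≥ 2 and the elimination system is
diagonal in practice).  Mid-plane symmetry is implemented as strict
parity — even-k cosines only — because even-k sine terms are
antisymmetric about ζ = λ/2; the alternative rule of zeroing odd-k
coefficients of both families is also provided (`odd_zero`), documented
as not actually symmetric.  The 1-DOF family is the lowest-order
symmetric member, R(ζ)/R₀ = 1 + (R_max/R₀ − 1)(1 − cos 2πζ/λ)/2; 2 DOF
adds the k = 4 cosine.  Shapes whose minimum radius falls below
0.2·R₀ (the occlusion floor, configurable) are refused at meshing.
The dilation window defaults to the centre of the capillary.

## Shape optimization

SLSQP (an SQP method) maximizes the FEM transfer rate over the free
coefficients, with central finite-difference gradients (step 10⁻³ of
the parameter scale) and explicit inequality constraints keeping the
wall extrema within [0.5, 2.5]·R₀ (prescribed bounds; a shipped test
verifies the 1-DOF optimum does not sit on them).  Feasibility of
random starts is obtained by shrinking toward the straight tube, which
is exact because R − R₀ is linear in the free coefficients.  Each
`optimize` call runs at least ten seeded random starts; degrees of
freedom are raised by continuation, each stage seeding one start from
the previous optimum (zero-padded into the nested family), which makes
the best transfer nondecreasing across stages by construction.  The
final optimum is re-evaluated at one mesh-refinement level and the two
transfer rates agree within 1% in the shipped configurations.  Results
are deterministic given the seed.  The 1-DOF optimizer is
cross-validated against a dense sweep of N versus R_max — the same
self-check used for the underlying physics.

## Morphometry of radius profiles

Two endpoint definitions quantify a dilation from a skeleton radius
profile r(s): `local_minima` (window between the two smoothed local
minima flanking the global maximum; R₀ = branch minimum) and
`average_crossing` (R₀ = arclength-weighted trapezoidal mean; window
between the crossings of the smoothed profile through R₀, located by
linear interpolation).  Raw skeleton radii carry voxel-quantization
noise, so endpoint detection runs on a moving-average smoothed profile
(default window 3 μm, always recorded in the output); R₀ and R_max are
taken from the unsmoothed data.  Only the single dominant dilation per
branch is measured.  Profiles with no interior maximum or missing
flanking minima/crossings yield an explicit "not detected" result, not
an exception.  Note the average-crossing definition is not self-inverse:
rebuilding a bump from its measurement and re-measuring reproduces λ
exactly only under the local-minima definition.

## Synthetic data

The generators emulate (i) skeleton radius profiles as sampled 1-DOF
cosine bumps with additive Gaussian radius noise (σ configurable,
default tests use 0.1 μm, a magnitude consistent with voxel-scale
scatter) and a 0.1 μm radius floor, and (ii) concentric-annulus
diffusion cases with their closed-form transfer rate.  They are pure
functions of their arguments and a mandatory seed, so all shipped
fixtures regenerate bit-for-bit.  What they do not emulate: branching,
centreline curvature, non-Gaussian quantization artifacts, or spatially
correlated noise — so passing the morphometry robustness tests bounds
performance on idealized bumps, not on arbitrary real skeletons.  The
packaged morphometry table ships measured geometric properties and
computed flow quantities for three reference 3D capillary images;
reproducing the 3D computed values themselves (resistances, velocity
maxima, numerical N_max) requires a 3D solver on the original surface
meshes and is out of scope.

## Numerical and design choices

* Regime thresholds, smoothing windows, occlusion floor, extrema
  bounds, SUPG/capturing coefficients and mesh defaults are all
  explicit keyword parameters with the defaults above.
* The discrete maximum principle is enforced as a hard check at
  [−ε, 1+ε], ε = 10⁻³ by default; linear elements cannot guarantee it
  at arbitrarily high Péclet numbers, hence the documented looser
  search-time level.
* Degenerate inputs fail loudly and early: zero villous distance
  (divergent annular bound), occluding shapes, empty dissociation
  samples, non-monotone saturation laws, inconsistent B constituents.
* The Lévêque exponent check must be run well above the
  equilibrated/Lévêque crossover pressure (≈450 Pa for the reference
  straight tube): closer to it, residual outflow saturation steepens
  the measured secant slope — a property of the physics, not the
  discretization.
* The two reported effective Péclet numbers for the dilation
  configurations follow from Pe_eff = B·u₀·R₀/D with u₀ the 300 μm/s
  centreline calibration (≈70 and ≈117); no other velocity scale is
  used.

## Known limitations

Axisymmetric geometry only (one dilation, straight centreline); no
red-blood-cell mechanics or radius-dependent viscosity; no tissue
oxygen consumption; linearized dissociation outside the nonlinear mode;
P1 transport limits sharp-front fidelity at Pe_eff ≫ 10³; the annular
bound and the Lévêque prefactor are order-of-magnitude tools when
applied to irregular real geometries.
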