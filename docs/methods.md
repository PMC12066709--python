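# Methods

This note documents the models implemented in `sanddbl`, their assumptions,
the defaults that matter, and the numerical choices — in enough detail that a
user can judge what a passing test suite does and does not demonstrate.

## Grain geometry and the cell-density chain

The sediment surface-to-volume ratio is S_V,T = 6(1−θ)·E[1/d_g]. By default
the expectation is the empirical sample mean of 1/d_g over the measured
diameter list — with samples of a few hundred grains, fitting and
integrating a density adds binning error without benefit; the
density-integral path exists and agrees with the sample mean within a few
percent for a log-normal fit to the same sample. Lengths are carried in µm
and converted to cm only inside this formula.

The rate chain runs: bulk volumetric rate (µmol O₂ L⁻¹ h⁻¹, per litre of
pore water) ÷ volumetric cell density (cells cm⁻³, from areal density ×
S_V,T) → cell-specific rate (fmol O₂ cell⁻¹ h⁻¹) ÷ characteristic cell
biovolume (0.4 µm³) → colony-scale volumetric rate (mmol O₂ L⁻¹ h⁻¹).
The printed constants of this chain are mutually inconsistent at the last
digit: −46 µmol L⁻¹ h⁻¹ over 1.3×10⁸ cells cm⁻³ and 0.4 µm³ gives
−885 mmol L⁻¹ h⁻¹, while the grain model's canonical consumer amplitude is
−955 mmol L⁻¹ h⁻¹. We therefore treat −955 as a stated model constant
(`GrainModelConfig.r_c_min_mmol_L_h`), not a derived one; the chain
functions compute the unrounded arithmetic.

Surface roughness of an outline is the radial difference between the
outline and its convex hull, measured from the outline's area centroid (the
centroid is rotation-stable; the hull radius is interpolated linearly in
polar angle between hull vertices). Convex outlines score exactly zero; the
measure is invariant under rigid motion and scales linearly with size.

## Ratiometric O₂ imaging

The sensor particles combine an O₂-quenched indicator (red) with an inert
reference dye (green); the red/green ratio cancels illumination and
bleaching gradients. Calibration fits R(C) = R₀/(1 + K_sv·C) (simple
Stern–Volmer) or the two-site variant R₀·(f/(1+K_sv·C) + 1−f); the two-site
model with f = 1 reduces exactly to the simple one. Rates are concentration
differences between two frames divided by the elapsed hours, assuming the
initial O₂ field is homogeneous.

Processing order is: invalidate pixels whose |rate| exceeds a threshold
(default 500 µmol L⁻¹ h⁻¹ — the workflow this mirrors sets a threshold
without printing a value), then apply a 5×5 NaN-aware median filter with
reflective borders. Whether thresholding preceded filtering in the original
workflow is not documented; this order is fixed here because it prevents a
spike from contaminating its neighbourhood median. The chlorophyll mask
defaults to Otsu's threshold on the autofluorescence image, overridable by
an absolute value.

The synthetic forward model (rate field → O₂(t) = clip(C₀ + R·t, 0, ∞) →
ratio images with multiplicative Gaussian channel noise) emulates
shot-noise-like, intensity-proportional error. It does not emulate optical
blur, sensor-particle density variation, 3D reflections off grain surfaces,
or bleaching beyond what the ratio principle cancels — so recovery tests
certify the inversion arithmetic and filtering, not robustness to every
imaging artefact.

## Single-grain flow and reactive transport

Geometry. The model is solved on a polar annulus from the grain surface
(radius r, default 145 µm) to an outer circle at 16 r, rather than on a
rectangular channel. The annulus lets the 5 µm reactive rim coincide exactly
with grid faces and makes the advective fluxes exactly conservative (below).
The outer-circle Dirichlet ring supplies solute from all directions, whereas
a channel with no-flux walls supplies only from its ends; 16 radii places
the ring's diffusive resistance (ln 16 ≈ 2.8) close to the supply-equivalent
of an 8r × 16r channel (≈ 2π) while erring on the generous side, i.e. the
stagnant-limit anoxia estimates are conservative. Only the diffusion-limited
corner (U ≲ 10 µm s⁻¹ at high O₂) is sensitive to this choice.

Flow. Stationary Stokes flow with no-slip on the grain and a uniform stream
U on the outer circle has the closed-form streamfunction
ψ = U·a·g(r/a)·sin θ with g = Aρ³ + Bρ ln ρ + Cρ + D/ρ; the four constants
follow from g(1) = g′(1) = 0 and g(β) = β, g′(β) = 1. Face-normal volume
fluxes are evaluated as streamfunction differences between face endpoints,
so the discrete velocity field is divergence-free to machine precision and
inflow and outflow through the outer circle balance exactly.

Transport. O₂ and N₂ satisfy steady advection–diffusion–reaction,
discretised finite-volume with first-order upwind advection and central
diffusion (harmonic-mean face diffusivities). The colony rate field follows
a thresholded sinusoid along the perimeter: with x = sin(aθ + φ), producers
occupy {x > √3/2} (arc = period/6 = 38 µm per pair on the default grain)
and consumers {x < −1/2} (arc = period/3 = 76 µm), bare surface between. A
plain "shifted sine" cannot yield 76 + 38 µm of colony out of a 228 µm
period, so thresholding is the only construction consistent with both the
printed arc lengths and the 2:1 consumer:producer split; within each arc
the rate ramps linearly in x to its extremum (−955 / +514 mmol L⁻¹ h⁻¹) at
the arc centre, approximating rates that decay from the colony core. The
phase puts a consumer-arc centre at the upstream stagnation point.

O₂ consumption is the potential rate times f_O₂ = C/(K_m + C) (K_m = 0.1
µmol L⁻¹); production (when enabled) enters unmodulated. The N₂ source is
the **potential** consumption magnitude × 1/10 × f_N = C_inh/(C_inh + C_O₂)
(C_inh = 0.1 µmol L⁻¹). Proportionality to the *realised* O₂ consumption
would be self-defeating — realised consumption vanishes exactly where
colonies are anoxic — so the potential-rate convention is the only one that
produces denitrification in anoxic microenvironments; it represents
heterotrophic capacity switching from O₂ to NO₃⁻ respiration.

Numerics. The nonlinear O₂ system is solved by a few implicit-Picard steps
(which preserve positivity) followed by Newton on the Michaelis–Menten
diagonal, to a relative residual ≤ 1e−8; N₂ is a single linear solve. The
default grid is 96 radial × 192 angular cells, four uniform cells across
the rim and geometric stretching outside. Steady-state mass balance closes
to ~1e−8 relative (the conservative-flux construction makes the 1 %
contract trivial); halving the cell size moves the anoxic fraction by
< 1 % at mid-range conditions. In the stagnant axisymmetric limit the
solver matches an independent two-point boundary-value solution of the 1D
diffusion–consumption problem within 5 %.

Outputs. "Anoxic" means C_O₂ < 1 µmol L⁻¹ (configurable; the source
workflow never defines it numerically). A colony counts as anoxic when more
than half its rim area is anoxic. Per-colony and per-grain N₂ production
extrude the 2D rim integral by one median grain diameter (290 µm,
configurable) — the 3D-per-grain units of the reference results from a 2D
model imply *some* extrusion convention, and one diameter is the natural
choice; reported values inherit its factor-order uncertainty. Under fully
anoxic colonies the default model yields ≈ 0.13 nmol N colony⁻¹ d⁻¹ and
≈ 0.5 nmol N grain⁻¹ d⁻¹.

Rim diffusivity can be scaled by an EPS factor (default 1.0; ~0.8 is a
plausible biofilm value) — the default keeps free-water diffusivities since
no printed correction factor is available.

## Sand_DBL scaling

δ = r/Sh with Sh = 1 + 0.62·Re^0.41·Sc^0.33 (Re = U·r/ν, Sc = ν/D) and
Sand_DBL = (δ²/D)·(R_O₂/C₀), with R_O₂ the colony-volumetric consumption
magnitude (default 955 mol m⁻³ h⁻¹, converted to SI) — the reaction–
diffusion analogue of a Damköhler number. The roughness correction is
first-order, δ′ = δ + c·roughness_max with c = 0.4, calibrated once so the
observed roughness range (2–35 µm) thickens the default grain's DBL by at
most ~20 % over pore velocities 10–100 µm s⁻¹ (only a bound, not a
functional form, is available to constrain it).

The anoxic-fraction law is refit from this package's own ensemble (the
original supplementary fit is not reproduced): a least-squares log–log line
through runs with fraction strictly inside (0.01, 0.99), clamped to 0 below
Sand_DBL = 10 and 1 above 1000. Two caveats are inherent and documented
rather than hidden. First, an unconstrained power law cannot be continuous
at the clamp thresholds; prediction is monotone and bounded in [0, 1] but
may step at 10 and 1000. Second, the PDE model's collective anoxia
transition is steeper in Sand_DBL than any single power law (a colony's
core and flanks go anoxic cooperatively), and the collapse across
velocities carries residual scatter, so cross-validated prediction error
against the PDE is ~0.2 RMS on partially anoxic runs while the rank
correlation exceeds 0.9. The fit is calibrated on advective runs
(U ≥ 50 µm s⁻¹): the Sherwood correlation is an advective mass-transfer
law, and stagnant runs do not collapse onto it.

## Areal upscaling

Hydraulic closures (bedform wavelength λ = 490·d_g, permeability
P = 9.869e−13·735·d_g²·1e−6 with d_g in µm, conductivity K = P·g/ν, head
h_m = 0.01·U², pore velocity U_pore = k·K·h_m) follow the printed empirical
chain. Two typesetting ambiguities are resolved on dimensional grounds: the
wavenumber is k = 2π/λ (the printed "λ/2π" is inverted), and the mixing
depth is z(t) = (1/k)·ln(1 + 0.42·k²·K·h_m·t/θ) (the printed form divides
by the logarithm, which would make depth shrink with time). The
permeability's trailing 1e−6 implies d_g enters in µm; this gives realistic
sand permeabilities (~6×10⁻¹¹ m² at 290 µm).

Penetration depths evaluate z at solute-depletion times t = C/R. The oxic
zone is split into four equal-thickness layers (equal-thickness vs
equal-O₂-drop is not specified; equal thickness is simpler and the linear
O₂ profile makes the difference small). O₂ declines linearly from the
bottom-water value to zero at z_O₂ — constant volumetric consumption along
the advective path gives a linear decline — and each layer's midpoint O₂
feeds its Sand_DBL. Colony rates for upscaling default to the biovolume
chain (the same scaling that produces −955 from −46); the 1/1000
pore-volume concentration path is exposed as an alternative. Rates are per
litre of pore water, so fluxes carry a porosity factor. The ±50 % band
reruns the chain with colony rates scaled by 0.5 and 1.5.

Seawater properties use a Sharqawy-type dynamic-viscosity correlation
(ν = µ/ρ with nominal ρ = 1025 kg m⁻³), the Garcia–Gordon (Benson–Krause)
O₂ solubility fit (µmol kg⁻¹ × 1.025 → µmol L⁻¹), and Stokes–Einstein
temperature scaling of D_O₂ from 1.1×10⁻⁹ m² s⁻¹ at 25 °C.

An emergent property worth knowing: the *share* of total denitrification
hosted by microenvironments is monotone non-increasing in bottom-water O₂,
but not strictly monotone in bottom-water velocity — faster flow deepens
the oxic zone (more microsite-hosting sand) at the same time as it thins
the DBL (fewer microsites per layer), and the share moves by only a few
percent across 0.1–0.2 m s⁻¹ while per-layer microsite prevalence falls
monotonically.

## Synthetic data

Grain diameters are log-normal (median 290 µm, geometric SD 1.3 — the
spread of the source distribution is not tabulated, so the GSD is a free
parameter chosen as typical for sieved sand). Outline roughness is a
band-limited Fourier perturbation (modes 5–25, 1/m amplitude weighting)
rescaled to a prescribed peak amplitude, which produces hull-measurable
indentations like real grain silhouettes. Colonisation maps place one
consumer and one producer arc per quarter-perimeter, sized by the colonised
fraction (default half the perimeter, split 2:1 consumer:producer). Site
tables draw log-uniform grain sizes (102–700 µm) and denitrification rates
(0.04–11.8 µmol N L⁻¹ h⁻¹), uniform bottom-water velocities (0.1–0.2
m s⁻¹), temperate T/S, and air-saturation bottom-water O₂. One integer
seed threads every generator; identical inputs give byte-identical outputs.

What passing tests show: the pipeline's arithmetic, conservation, limiting
cases and scaling behaviour are correct on inputs with the stated
statistical structure. What they do not show: agreement with any particular
field site (per-site inputs are not part of this package), robustness to
imaging artefacts outside the noise model, or 3D grain-shape effects (the
grain is a cylinder section; roughness enters only through the DBL
correction).

## Problem sizes

The default single-grain grid is 96 × 192 cells (~18k unknowns; one solve
takes on the order of a second). The test-suite ensembles use 20 runs for
the phase-diagram checks and 24 advective runs for scaling-law calibration;
the acceptance script performs one solve at the default grid.
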