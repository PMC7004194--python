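# Methods

## Scope and model structure

The package models the dissolution pharmacokinetics of CuO
nanoparticles in amino-acid media: complete power-law dissolution for
the pure oxide, and a two-step (burst + solid-state-diffusion-limited)
release for Fe-doped particles. It covers forward simulation,
parameter estimation and synthetic data; it does not model particle
synthesis, speciation/precipitation chemistry of the Cu–amino-acid
complex, the CuFe₂O₄/Fe₃O₄ phase transformation, iron release (taken
as zero), polydisperse size distributions, or any cellular/biological
response.

All internal quantities are strict SI (m, s, mol m⁻³, kg m⁻³); only
the file/CLI boundary speaks hours, mM, nm and µg/mL. This keeps the
rate constant's units — which depend on the orders, k_Cu has units
mol^(1−m−n) m^(3(m+n−1)) s⁻¹ — in one convention.

## Pure-CuO dissolution

Assumptions: a single rate constant per condition; rate proportional
to the surface copper concentration to power m and to the free amino
acid to power n; 1:2 Cu:ligand complexation depleting the ligand pool;
surface copper proportional to the active surface area of shrinking
monodisperse spheres at constant particle number, hence
A(t) = A₀ (1 − c/c_tot)^{2/3}. Temperature is not a variable (one
experimental temperature; no Arrhenius term).

The ODE is integrated with LSODA at relative tolerance 1e-8, with
states clamped at zero and a terminal event when copper or ligand is
exhausted; the rate law is non-Lipschitz at depletion, which the
clamp + event treatment handles. An `excess` switch on the medium
treats the ligand as an infinite reservoir; the default depletes it.

Two cheap exact symmetries are used as test oracles: scaling k_Cu by α
equals scaling time by α (autonomous ODE), and the t = 0 slope is
k_Cu (k_#,s A₀)^m c_AA,0^n.

## Two-step doped dissolution

The burst applies the pure rate law to the finite surface copper
inventory (1 − f_Fe,0) k_#,s A₀ at fixed total surface area; the
surface iron fraction f_Fe,s(t) = 1 − c_s(t)/(k_#,s A₀) rises from
f_Fe,0 to 1. The long-term step is desorption from a sphere with zero
surface copper (f_Fe,s = 1 from the start of the component),
c(x, 0) = 1 in the bulk, fixed radius R = d₀/2 (the insoluble iron
scaffold persists; TEM-style shrinking is not modelled). Both
components run from t = 0 and are summed; because the burst is fast
relative to the tail, starting the diffusion clock at burst completion
would change the curves negligibly. An earlier moving-boundary
formulation of the same physics does not conserve mass and is
deliberately not implemented; the split superposition is the model.

The amino acid is depleted by the burst but treated as non-limiting
during the diffusion phase, whose bottleneck is solid-state transport;
at the default design (5 mM ligand vs ≤0.16 mol m⁻³ copper) the
distinction is invisible.

Mass balance: every simulated curve carries its inventory bookkeeping
(burst inventory, bulk inventory, remaining copper at the final time),
and `check_mass_balance` re-derives the initial copper from the
particle description and checks released + remaining = initial at
relative error < 1e-6. Failures are reported, not raised.

## Radial diffusion numerics

The dimensionless problem ∂c/∂τ = ∂²c/∂x² + (2/x)∂c/∂x, c(1, τ) = 0,
zero-flux symmetry at the centre, is discretised on a node-based
uniform grid (n_nodes intervals) with the centre node handled by the
spherical limit 3∂²c/∂x² → 6(c₁ − c₀)/Δx², and marched with explicit
Euler. The conservative stability bound Δτ ≤ Δx²/6 is enforced
(violations raise, naming the bound); the default step is Δx²/8. The
released fraction M(τ) = 1 − 3∫₀¹ c x² dx uses the trapezoidal rule
with the x = 0 node contributing zero. At τ = 0 the initial condition
has a jump exactly at the surface node, which the trapezoidal rule
would mis-charge by 1.5Δx; since nothing has been released, M(0) = 0
is reported exactly. At 200 nodes the scheme agrees with the analytic
series to L∞ < 1e-3 over τ ∈ [0, 1] and converges at second order in
Δx.

`released_fraction_series` is the exact solution: the eigenfunction
sum 1 − (6/π²) Σ k⁻² exp(−k²π²τ) with the term count chosen for
truncation error < 1e-10, switching below τ = 0.01 to the equivalent
theta-transformed short-time form 6√(τ/π) − 3τ whose error there is
O(exp(−1/τ)). Production simulation uses the series (exact and fast —
realistic τ values are ~1e-8–1e-4, where the finite-difference scheme
would need a boundary-layer-resolving grid); the explicit scheme is
retained as the PDE solver and the two are cross-checked in the test
suite.

## Parameter estimation

All optimisation is in log₁₀ parameter space (positivity; D spans
decades). Residuals are plain concentration residuals and the loss is
the unweighted mean square error.

* Pure fits: bounded scalar minimisation over log₁₀ k_Cu (golden
  section/parabolic), bracket = initial-slope guess ± 6 decades,
  xatol 1e-7. A solution pinned at a bracket edge is flagged
  not-converged (e.g. identically zero data drive k_Cu to the lower
  bound).
* Doped fits: bounded least squares (`trf`) over
  (log₁₀ k_Cu, log₁₀ k_#,s, log₁₀ D), any subset fixable. Starts: one
  deterministic data-driven warm start (the burst plateau pins k_#,s
  through the surface inventory; the initial slope then pins k_Cu)
  plus a seeded Latin hypercube (8 by default); the best of all
  converged starts is returned with every attempt in the diagnostics.
  If the data do not extend well past the burst — observations
  < 3× the time of the log-time rate peak, or the smoothed rate never
  falls below half its peak — D is declared unidentifiable, fixed at
  0, and a warning raised.
* Order scan: for each (m, n) on the grid (defaults
  m ∈ {1.00 … 2.50 step 0.25}, n ∈ {1, 2, 3}), k_Cu is fitted per
  initial-concentration curve and regressed on the initial CuO
  molarity. The selection minimises the dimensionless
  |slope| · (c_max − c_min) / mean(k_Cu); ties within a relative 1e-9
  fall back to the smaller mean MSE. The dual criterion (independence
  first, MSE as tie-break) makes the stored grid sufficient to
  reproduce the selection.

Residual-bootstrap uncertainties are deliberately not computed by
default; the headline outputs are point estimates and selection
diagnostics.

## Synthetic data

The generator emulates the dissolution study: 250 h horizon, t = 0
plus 40 log-spaced samples from 0.1 h; doping levels 0/1/6/10 at%;
threonine, valine, isoleucine, serine at 5 mM; d₀ = 10 nm at
12.5 µg/mL; plus a pure-CuO series at 6.25/12.5/25 µg/mL in valine for
the order scan. Defaults for the truth table: k_#,s = 1.66e-5 mol m⁻²
(≈10¹⁹ sites m⁻², a typical oxide surface atom density; it is a fit
parameter everywhere it matters), D = 1e-27 m² s⁻¹ for doped
particles, orders (1.75, 2), and k_Cu = 1e-4 · aa · exp(−12 f_Fe,0)
with amino-acid factors {thr 1.2, val 1.0, ile 0.8, ser 0.6}. The
k_Cu table was set, before freezing, by forward-simulating the design
until the curves show the qualitative structure the model predicts:
pure CuO dissolving essentially completely within the window, doped
bursts plateauing well inside 250 h so the log-time rate exhibits the
two-process signature, and adjacent doping levels separated (11–45 %)
by clearly more than the three-parameter fit's noise-driven spread in
k_Cu (~5 %, dominated by the k_Cu–k_#,s collinearity of the burst).

Noise is independent multiplicative Gaussian (sd 3 %, an assumption
recorded in the manifest — UV/Vis-derived concentrations err roughly
proportionally to signal), clamped at zero; noisy curves are not
forced monotone. A single seed makes the dataset byte-reproducible,
and the manifest records every generating parameter.

What passing tests on these data do **not** show about real
measurements: real replicate noise structure (correlated drifts,
baseline errors) is not emulated; polydispersity and aggregation are
absent, so recovered parameters on lab data will carry model-mismatch
bias the synthetic round-trips cannot reveal; and the amino-acid
selectivity factors are placeholders, not calibrated chemistry.

## Problem sizes

Default runs are desk-scale by construction: 41-point curves, 21-pair
order scans over three concentrations (~3 s), nine-start doped fits
(~1–3 s each), 200-node diffusion solves to τ = 1 (~5 s). The
acceptance script completes in a few seconds.

## Known limitations

* The two-step superposition ignores burst–diffusion coupling (the
  diffusion boundary condition is c = 0 from t = 0 even while surface
  copper remains); accurate because the phases are time-separated,
  inaccurate if k_Cu were so small that the burst lasted as long as
  the tail.
* k_Cu's units change with (m, n); comparing rate constants across
  order pairs is only meaningful through the curves themselves.
* The order scan assumes a shared amino acid within a concentration
  series; the CLI enforces this by scanning the amino acid with the
  most concentrations.
* D is reported per condition; the model has no temperature or
  composition dependence of D.
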