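# cuokinetics

Model-based pharmacokinetics of Cu²⁺ release from pure and Fe-doped CuO
nanoparticles.

CuO nanoparticles dissolve in amino-acid media and act as a copper-ion
source; doping the lattice with iron turns an uncontrolled burst into a
tunable sustained release, which is what makes these particles
interesting as nanomedicine. This package implements the kinetic model
behind that behaviour — forward simulation, parameter estimation, a
synthetic-data generator emulating the dissolution-study design, and a
small CLI — for researchers who want to fit or design ion-release
curves rather than re-derive the model.

## The model

**Pure CuO** dissolves completely through a power-law surface reaction.
With `c` the cumulative dissolved Cu²⁺ (mol m⁻³):

    dc/dt = k_Cu · c_s(t)^m · c_AA(t)^n

* `c_s = k_#,s · A(t)` — surface copper concentration; `k_#,s` is the
  atomic surface density (mol m⁻²) and `A(t) = A₀ (1 − c/c_tot)^{2/3}`
  the active area of shrinking monodisperse spheres at constant
  particle number.
* `c_AA(t) = c_AA,0 − 2c` — free amino acid; Cu²⁺ and amino acids
  complex 1:2 at physiological pH, so dissolution consumes ligand.
* `m`, `n` — partial dissolution orders, selected by the
  concentration-independence criterion: the correct pair makes the
  fitted `k_Cu` invariant to the initial CuO concentration
  (`dk_Cu/dc_CuO,0 ≈ 0`), with the mean square error breaking ties.
  On the package's synthetic curves the scan selects `(m, n) = (1.75, 2)`.

**Fe-doped CuO** releases copper in two superimposed steps. During the
burst, the same rate law empties the copper share of the surface-site
inventory `(1 − f_Fe,0) k_#,s A₀` while the surface iron fraction
`f_Fe,s` rises from the doping level `f_Fe,0` to 1; the insoluble iron
shell then terminates surface dissolution. Long-term release continues
only by solid-state diffusion of bulk copper through the scaffold:
Fick's second law in a sphere with zero surface concentration,
`∂c/∂τ = ∂²c/∂x² + (2/x)∂c/∂x` on `x = r/R ∈ [0,1]`, `τ = D t/R²`,
solved by an explicit radial finite-difference scheme and
cross-checked against the eigenfunction series
`M(τ) = 1 − (6/π²) Σ k⁻² exp(−k²π²τ)`. The total curve is

    total(t) = burst(t) + bulk_inventory · M(D t / R²)

with `D ~ 10⁻²⁷ m² s⁻¹` at room temperature — negligible in bulk
oxides, decisive at the nanoscale. Copper mass balance
(released + remaining = initial) is audited on every simulated curve.

## Worked example

```python
import numpy as np
import cuokinetics as ck

particle = ck.ParticleSystem(d0=10e-9, f_fe0=0.10, mass_conc=0.0125)  # 12.5 ug/mL
medium   = ck.MediumSpec(amino_acid="valine", c_aa0=5.0)              # 5 mM
params   = ck.paper_like_params(0.10, "valine")                       # truth table
times    = np.concatenate(([0.0], np.geomspace(360.0, 250 * 3600.0, 40)))

curve = ck.simulate_doped_release(particle, medium, params, times)
print(f"burst inventory {curve.meta['burst_inventory']:.4e} mol m^-3")
print(f"total at 250 h  {curve.total[-1]:.4e} mol m^-3")
print(ck.check_mass_balance(curve, particle))

res = ck.DopedReleaseModel(curve.as_release_curve(), particle, medium).fit(seed=0)
print(res.summary())
```

prints

```
burst inventory 1.7758e-02 mol m^-3
total at 250 h  2.0018e-02 mol m^-3
mass balance PASS: initial 1.414205e-01, released 2.001807e-02, remaining 1.214024e-01 mol m^-3 (relative error 0.00e+00)
Release-curve fit
==============================================
  k_Cu     3.01194e-05   (log10  -4.5212)
  m               1.75
  n                  2
  k_#,s    1.66000e-05 mol m^-2
  D        1.00000e-27 m^2 s^-1
----------------------------------------------
  MSE        1.178070e-30 (mol m^-3)^2
  n points   41
  starts     9
  converged  True
```

Reading the numbers: one monolayer of surface sites holds 1.78 × 10⁻²
mol m⁻³ of copper (≈13 % of the 0.141 mol m⁻³ total) — the burst dose,
set purely by `d₀`, `f_Fe,0` and `k_#,s`. By 250 h the diffusion tail
has added another ~2 % of the bulk inventory. The three-parameter fit
(rate constant, surface density, diffusion coefficient; bounded least
squares in log₁₀ space, seeded Latin-hypercube multi-start) recovers
the generating parameters essentially exactly on this noise-free curve.

The same workflows are scriptable from the shell via the `cuokin`
console entry point (`simulate`, `generate`, `fit`, `scan-orders`,
`validate`); see `cuokin --help`.

## Layout

* `cuokinetics.particles` — particle/medium descriptions, molar inventories
* `cuokinetics.pure` — pure-CuO power-law dissolution ODE
* `cuokinetics.doped` — burst + radial-diffusion two-step model, mass balance
* `cuokinetics.fitting` — `PureReleaseModel`, `DopedReleaseModel`, `OrderScan`
* `cuokinetics.synthetic` — study-design emulation with ground-truth manifest
* `cuokinetics.io` / `cuokinetics.cli` — CurveTable CSV, configs, `cuokin` CLI

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
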