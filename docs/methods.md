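# Methods

## Model

The simulator tracks a particle population in a quiescent liquid column of
height L above a cell monolayer, jointly with dissolved silver in three
pools (free, protein-bound, cell-associated). The state is the number
density N(D_p; x, t) — particles per metre of column depth per nanometre of
core diameter — plus the ion concentrations C_f, C_p, C_cell (µg/mL, all
referenced to the media volume).

Assumptions: spherical particles; transport only along the column depth by
Brownian diffusion and gravitational settling (no convection); no
agglomeration, coagulation or break-up during a run; ions well mixed
(uniform over the column); dissolution only in the media, never inside
cells; particles arriving at the cell layer are taken up instantly under
the default absorptive boundary.

Protein-coated particles are transported at the coated diameter
D_pc = D_p + 2ΔR_c with the measured effective density ρ_pc, while mass,
number, volume and surface area always use the core diameter and the
primary material density — the corona is silver-free bookkeeping.
Agglomerates use the Sterling settling law with a porosity-derived density
(fractal dimension DF), expose the total surface of their primary
particles, and shrink faster by the factor a = D_p/D_p1.

Ion kinetics: silver leaves particle surfaces through three
surface-area-limited channels (free pool, slow protein pathway, fast
protein pathway with capacity n₂·P₀, n₂ = n₂c·n·P₀^−0.403); free and bound
silver also exchange directly. Driving terms are signed — a pool above its
capacity transfers back; nothing is clamped. Cellular uptake is
diffusion-limited across the membrane: the solver uses the *lumped* law,
flux = D₁₂·SA₂/(V·Dis₂) · (C_f + C_p − (C_cell·V/V_cell)/PC₂₁), with the
media-side loss split between the free and bound pools by their
concentration share. The per-phase alternative (each pool separately
relaxed toward the cell equilibrium) is exposed as `ion_rhs_with_cells` for
completeness, but summing its two efflux terms doubles the cell-to-media
return flux and halves the equilibrium cell burden; the lumped law is the
form the uptake parameters were calibrated under, and it is what the
bundled scenario predictions assume. The ion-only exposure model
(`ion_uptake_only`) starts with 85% of the administered ions protein-bound,
reflecting the bound:free ratio observed in serum-containing media.

## Parameters

Defaults are the calibrated silver/RPMI+FBS system (all configurable):

| parameter | default | units | meaning |
|---|---|---|---|
| L, V, A | 3.15 mm, 3 mL, 9.52 cm² | | column height, media volume, well-bottom area |
| T, μ, ρ_f | 310 K, 7.4e-4 N·s/m², 1 g/mL | | media temperature, viscosity, density |
| D_p1, ρ_p1 | 20 or 110 nm, 10 g/cm³ | | core diameter, silver density |
| ΔR_c, ρ_pc | 12 / 22.5 nm, 1.583 / 1.914 g/cm³ | | corona thickness, effective density |
| D_min | 10 nm | | dissolution floor (inert core) |
| k_f, C_sat | 6e-18 mL·nm⁻²·h⁻¹, 1 µg/mL | | particle→free channel |
| k_p, k_p2 | 3e-17, 1e-15 mL·nm⁻²·h⁻¹ | | slow / fast particle→protein channels |
| k_f2p, k_p2f | 0.0114, 0.016 µg⁻¹·mL·h⁻¹ | | free↔bound exchange |
| n, n₂c | 0.4 µg·mL⁻¹·FBS%⁻¹, 1.2534 | | binding-site capacity, fast-site pre-factor |
| D₁₂, Dis₂ | 9.02e-9 cm²/h, 7.8e-7 cm | | membrane diffusivity, thickness |
| PC₂₁, V_cell | 25.8, 1.936e-3 mL | | partition coefficient, total cell volume |
| SA₂ | 9.52 cm² | | total cell surface area |

SA₂ is not part of the published parameter set; the package defaults it to
the well-bottom area (a confluent monolayer). At 24 h the cell ion pool is
essentially at its partition quasi-equilibrium, so the 24 h predictions are
insensitive to this choice; short-time uptake kinetics are not.

Rate constants are stored in their calibrated units. Internally: x in m,
D_p in nm, t in h, mass in µg, concentration in µg/mL, areas in nm². The
unit layer converts once at configuration load; 1 g/cm³ = 1e-15 µg/nm³.
Physical constants: g = 9.80665 m/s², k_B = R/N_A (CODATA).

## Numerical scheme

Node-centred grid: x from 0 (surface) to L (cells), default Δx =
3.1532e-6 m; D_p from the dissolution floor to the top of the initial size
support, default ΔD_p = 1 nm. All integrals use trapezoidal quadrature.

Each master step (default 0.02 h, reduced if the size-advection CFL
requires) applies sequential operator splitting:

1. **Vertical transport**, per size bin: finite-volume fluxes with upwind
   advection and central diffusion, advanced by Crank–Nicolson with two
   backward-Euler startup steps (Rannacher smoothing of the initial
   boundary-layer discontinuity at the absorbing wall). Coefficients are
   time-independent, so each bin's tridiagonal operator is LU-factorized
   once. Top face: zero total flux. Bottom: absorptive (node pinned at
   zero), no-flux, or Robin N = α·J (α in h/m; α = 0 recovers absorptive,
   α → ∞ no-flux). Deposition per bin is the quadrature-weighted count lost
   in this substep — exact bookkeeping by construction; particles are
   recorded in the cell inventory at their size at deposition.
2. **Size advection**: explicit conservative upwind in D_p at the shrink
   rate implied by the current ion state, sub-cycled to CFL 0.5. No flux
   crosses either size boundary: cores accumulate at the floor (and are
   excluded from the dissolvable surface area); the upper boundary reflects
   (only reachable in supersaturated media).
3. **Ion kinetics**: one RK4 step. The particle source is the *exact*
   discrete silver mass shed in substep 2, divided by V·Δt and apportioned
   across the three kinetic channels in proportion to their driving terms.
   This replaces the nominal k·Area/V source terms inside the solver so
   that total silver (media particles + cell particles + V·(C_f+C_p+C_cell))
   is conserved to round-off rather than to the O(ΔD_p) mismatch between
   the discrete advection mass loss and the quadrature surface area; the
   literal kinetic forms remain available as `ion_rhs_media_only` /
   `ion_rhs_with_cells` and are what the well-mixed reference integrator
   uses.

Particle number (media + cells) is conserved exactly; the balance ledger
records both at every output time and the test suite asserts drifts below
1e-9 (the nominal tolerances are 1e-3 for mass and 1e-6 for number).
Negative densities beyond 1e-8 of the field maximum abort the run;
round-off-level negatives from the implicit solve are zeroed. Halving both
grid spacings changes the 24 h deposited mass of the 20 nm reference
scenario by ~0.4%.

The absorbing condition N(L) = 0 is inconsistent with the uniform initial
field at t = 0⁺; the initial bottom half-cell (≈Δx/2L ≈ 0.05% of the dose)
is absorbed in the first step and counted as deposition.

The cell-free vial model (`dissolve_well_mixed`, used for calibration and
as a solver cross-check) integrates the same kinetics with Lagrangian size
classes — characteristics in D_p, no size-grid diffusion — via
`scipy.integrate.solve_ivp` (LSODA, rtol 1e-8).

## Calibration and identifiability

Fits run in log10 parameter space with bounded `least_squares` (TRF),
residuals weighted by the inverse datum (relative error — the measured
concentrations span more than a decade), multi-start: the first start is
the current configuration values, further starts are drawn log-uniformly
within ±2 decades (seeded, recorded in the result). n₂ is never fitted
directly; the pre-factor n₂c is.

Sensitivity functions are central finite differences at ±10% of each
parameter, normalized by the mean output magnitude. The collinearity index
of a parameter subset is 1/√λ_min of the Gram matrix of unit-normalized
sensitivity columns; subsets under 20 are conventionally identifiable. For
the serum-level design (one dose, three FBS levels) the lowest-index
6-parameter subset is {k_f, C_sat, k_f2p, k_p, k_p2, n₂c} (index ≈ 14).
Identifiability in this sense does not guarantee tight recovery: with 5%
multiplicative noise the Cramér–Rao bound on k_f, k_f2p and k_p exceeds
45% relative error under that design, and the recovery study reflects
this — only C_sat, k_p2 and n₂c (and, at lower noise, k_p) come back
tightly. Richer designs (multiple doses, which vary Area(t) independently
of the protein capacities) condition the problem much better.

## Synthetic data

`synthesize_timecourse` generates vial dissolution (C_diss(t)) and ion-only
uptake (cell silver mass) datasets from the forward models with
multiplicative Gaussian noise, value·(1 + sd·ε), clipped at zero and
deterministic given a seed. It emulates the measurement designs used to
calibrate the kinetic submodels (time courses over 1–24 h across serum
levels and doses). It does not emulate inter-replicate biological
variability, detection limits, matrix effects in the silver assay, or
centrifugation artefacts in the particle/ion separation — passing recovery
tests demonstrate estimator correctness under the stated noise model, not
robustness to real measurement pathologies.

## Design choices and limitations

- **Shrink-rate density.** The shrink rate uses the primary material
  density ρ_p1, the form consistent with the surface-flux mass balance.
  With the calibrated rate constants this caps shrinkage at ≈0.42 nm/h in
  fresh media: the 20 nm system just reaches the 10 nm floor within 24 h;
  the 110 nm system ends near 100 nm. Published reference simulations for
  the same systems show a wider 24 h size span (down to 78 nm for the
  110 nm system), consistent with the *effective* transported density
  having entered that term instead; the package keeps the mass-consistent
  form.
- **Per-size-bin tail counts are scheme-dependent.** Quantities like "the
  number of particles still in the initial size bin after 24 h" are tails
  of the numerically diffused size distribution and depend on the upwind
  discretization and the (unpublished) width of the initial distribution;
  they are not reproducible across schemes, unlike the integral observables
  (masses, concentrations, deposited fractions).
- The default initial distribution is monodisperse at the primary diameter
  (a delta), which reproduces the analytic initial counts exactly; a
  truncated Gaussian (never below the primary size, renormalized) and
  empirical tables are supported.
- Buoyant particles (ρ_pc < ρ_f) are clamped to zero settling in the
  bottom-flux sense; upward advection is handled by the upwind fluxes but
  no bundled scenario exercises it.
- No dynamic agglomeration, no intracellular dissolution, no speciation
  chemistry, 1-D geometry only.
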