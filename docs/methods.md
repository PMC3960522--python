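# Methods

## The biomass-coupled kinetic model

The model tracks the concentrations (mM) of 31 dynamic species — substrates
(methanol, acetate), gases (CH4, CO2, CO), the C1-carrier pools
(tetrahydrosarcinapterin and its methyl/methylene/methenyl/formyl forms,
methanofuran, coenzyme M, coenzyme B and their derivatives), the redox
carriers (F420, ferredoxin, methanophenazine), the adenylate pool
(ATP/ADP/Pi), and the extracellular ion pool — plus the cell mass (mg) in a
fixed 1 mL compartment. Water, the intracellular proton, and the cytosolic
sodium pool are held constant: they appear in the stoichiometry for
completeness but are never updated, and their kinetic effect is folded
into the rate constants.

Reversible enzymes appear as two independent irreversible reactions, each
with its own `k_cat`; no thermodynamic (Haldane) consistency is enforced
between the two directions, because the parameterisation fixes both
independently. Three mechanisms are used:

- **M** — unimolecular Michaelis–Menten, `v = k_cat·E·s/(K_M+s)`.
- **B / B-C** — bimolecular Michaelis–Menten with shared `k_cat` and `K_M`
  for both kinetic substrates. The algebraic two-substrate form is not
  uniquely determined by that statement; this package uses the
  multiplicative closure `v = k_cat·E·[s1/(K_M+s1)]·[s2/(K_M+s2)]`, which
  preserves the per-substrate half-saturation meaning of `K_M` and the
  `k_cat·E` ceiling. For B-C rows (more than two reactants) the remaining
  co-reactants are converted at the same flux, which implements the
  constant-flux side reaction; a kinetic substrate that is a constant
  species (water in the CO-dehydrogenase direction) contributes a
  saturation factor of 1.
- **F** — first order; the single F reaction is the cell-mass reaction
  `ATP → ADP + Pi + biomass` at `k = 0.125 h⁻¹` (stored internally in s⁻¹),
  depositing 15.4 g of biomass per mole of ATP.

**Enzyme levels.** Enzymes are an algebraic function of the current cell
mass: `E_i(mM) = a_i(µmol/mol ATP) · M(mg) / (15.4·10³ · V(mL))`. This is
exactly equivalent to carrying each enzyme as a linearly-coupled ODE state
(the cell-mass reaction produces enzymes in fixed proportion to ATP
throughput) but uses fewer states and keeps the initial enzyme levels
consistent with the 0.1 mg inoculum. The allocation stoichiometries are
shipped verbatim for the methanol- and acetate-grown conditions; they can
also be recomputed from an RPKM + molecular-weight table via the
mass-fraction route in `growth` (the two shipped methyltransferase entries
were adjusted in the source tables to match protein-level measurements, so
the verbatim tables are authoritative).

**Translocated ions.** HdrDE and Fpo pump protons; Rnf and the
methyl-transferase Mtr pump sodium; ATP synthase consumes 4 translocated
ions per ATP (3.5 is available as the `h_per_atp` option). By default the
package routes pumped Na⁺ into the same extracellular ion pool that drives
ATP synthase (`pool_translocated_ions=True`), a chemiosmotic equivalence
that reflects the promiscuous Na⁺/H⁺ coupling of the organism's A1AO ATP
synthase. This choice is load-bearing for acetoclastic growth: with sodium
held constant, acetate uptake (1 ATP per acetate at acetate kinase)
strictly exceeds the 0.5 ATP per acetate recoverable from HdrDE proton
pumping alone, and the pathway cannot sustain growth at all.

**Initial conditions (study defaults).** 125 mM methanol or 120 mM
acetate; 0.1 mg cell mass; ATP/ADP/Pi = 10/1/10 mM; every carrier pool at
0.009 mM (by default the free/oxidised member of each conserved pool
carries the whole pool; `carrier_init="all"` initialises every carrier
species instead); extracellular pH 7 (10⁻⁴ mM ionic pool).

## Numerics

The ODE system is integrated in seconds with LSODA (stiff-capable,
`rtol = 1e-8`, `atol = 1e-10` mM), sampled on a dense output grid
(`sample_h`, default 0.01 h; long runs use coarser grids). Rate laws are
evaluated on non-negatively clipped state views. Because B-C side
reactions and M-type co-reactants do not appear in their own rate law, a
reaction could otherwise drive such a pool slightly negative; each
reaction's flux is therefore multiplied by a smooth depletion guard
`s/(s+ε)`, `ε = 10⁻⁶ mM`, for every non-kinetic dynamic reactant. The
guard leaves stoichiometry untouched, so all conservation laws hold
exactly; its influence is confined to the sub-nanomolar regime.
Integration stops at substrate exhaustion (10⁻³ mM) via a terminal solver
event; accepted states are never mutated.

Moiety-pool and carbon conservation hold to 1 part in 10⁶ along
trajectories (asserted in the test suite), and a fixed-step RK4
integration agrees with the adaptive solver to 10⁻⁴ relative (species
below 10⁻⁴ mM compared absolutely at that floor) on a 1 h methanol
window.

## Observables

- **Peak methane production rate** — maximum central-difference derivative
  of cumulative CH4 on the dense output, reported in nmol·mL⁻¹·min⁻¹, with
  no smoothing beyond the output grid.
- **Efflux ratio** — cumulative CH4 divided by cumulative CO2 at the final
  time (net gas amounts in the compartment).
- **Growth rate** (sensitivity observable) — peak of `d(ln M)/dt`
  excluding a 20 h burn-in. The burn-in removes the initial relaxation of
  the 10 mM ATP pool, which converts to biomass at the first-order
  cell-mass rate regardless of enzyme levels and is therefore blind to the
  perturbations being ranked.

## Sensitivity analysis

`s = (x/Y)·∂Y/∂x` is estimated by central differences at δ = 5%. Enzyme
copy-number perturbations scale that enzyme's allocation stoichiometry
(equivalently its concentration at every cell mass). Enzymes are ranked by
|s| with ties broken alphabetically; integration failures are flagged per
enzyme without aborting the scan. Rankings use a 400 h window — long
enough that the post-burn-in growth signal reflects pathway flux — and
complete in a few minutes for both conditions together.

## Rate-constant fitting

Any subset of reaction `k_cat` values can be fitted to substrate and
culture-mass observations (mass via the 0.41 mg/mL-per-OD420 calibration).
Residuals weight each series by its reciprocal maximum so substrate (mM)
and mass (mg/mL) contribute comparably. Optimisation is bounded least
squares in log-parameters, multi-started from the table value plus seeded
Latin-hypercube points (default bounds 0.01–100× the table value, 8
starts); the finite-difference step (1% in log-space) is set so Jacobians
clear the ODE-solver noise floor. The 6.8 reverse:forward ratio used for
the oxidation-branch pairs is available as a `ratio_ties` constraint.
Fits are bit-reproducible for a fixed seed. Recovery experiments
(simulate → corrupt → refit) report per-parameter bias and RMSE; noiseless
single-parameter recovery is exact to optimizer tolerance.

## Copy-number arithmetic

Copies per cell = `conc(nM)·10⁻⁹·N_A·10⁻³ / cells·mL⁻¹`, with relative
uncertainties combined in quadrature. The Avogadro constant is fixed at
the rounded 6.023×10²³ mol⁻¹, the value under which the published
per-cell ribosome counts (10038, 18135) reproduce exactly; the SiMPull
protein rows reproduce within 0.5% from the rounded printed
concentrations. The proteome route converts dry mass × protein fraction ×
proteome mass fraction through the complex's molecular weight. The spot
calibration line is fitted with a free intercept, as no functional form
beyond linearity is established.

## Morphometry

DIC images show the directional derivative of optical path length along
the shear axis. `hilbert_enhance` normalises the image to zero mean and
unit scale, rotates the shear direction onto image rows (bilinear
resampling, reflective padding), applies a row-wise Hilbert transform,
rotates back, adds the transform to the original, and rescales to [0, 1] —
for a derivative signal the transform is an |ω|-filtered copy of the
underlying indicator, restoring a thresholdable interior. Segmentation
thresholds a lightly smoothed enhanced image at median + 4×MAD-σ (robust
when cells cover a small area fraction, where a two-class global threshold
is unstable), removes small and border-touching objects, splits touching
cells by a distance-transform watershed, and refines each cell to a
fractional-peak contour (fraction 0.15, calibrated on phantoms) to shave
the slowly-decaying Hilbert tails along the shear axis. Axes are the
region's best-fit ellipse axes × pixel size; volume is the prolate
spheroid (π/6)·L·W², since a 2-D image shows only two axes. On phantoms at
SNR 10 the pipeline recovers all cells with mean axis errors of about +4%
(length) and −1% (width).

## Synthetic data

The generators emulate the statistical structure each consumer assumes:
log-normal RPKM with uniform 20–600 kDa molecular weights; growth curves
simulated from the model itself (ground-truth parameters recorded) with
additive Gaussian noise scaled to each series' maximum; Poisson spot
counts around a known calibration line; and DIC phantoms rendered as the
directional derivative of a blurred ellipse-indicator field (σ = 1.5 px)
plus white noise at a stated SNR — the minimal appearance model under
which Hilbert enhancement is the correct inverse. Cell sizes default to
the measured means (2.9/2.3 µm methanol-grown, 2.3/1.7 µm acetate-grown)
with ~15% coefficients of variation; 0.1 µm/px, 512² images, and
non-overlapping placement are the imaging defaults. The phantoms do not
model a realistic microscope PSF, shot noise, uneven illumination, or
confluent cell clusters, so passing recovery tests demonstrate the
correctness of the inversion and measurement chain, not performance on
real micrographs.

## Known limitations

- **Absolute methane rates.** Under the shipped parameterisation the peak
  methane production rates are ~0.2 (methanol) and ~0.01 (acetate)
  nmol·mL⁻¹·min⁻¹ — three to four orders of magnitude below the published
  565 and 269. This is structural, not numerical: with carrier pools of
  0.009 mM and the methyl-coenzyme-M reductase parameters
  (k_cat = 5 s⁻¹, K_M = 2 mM, 321.8 µmol/mol ATP), methane flux is bounded
  by `k_cat·E·(pool/(K_M+pool))² ≈ tens of nmol·mL⁻¹·min⁻¹` at final
  biomass, and no saturating two-substrate closure can exceed the
  single-substrate bound. Even granting the most favourable readings
  (100× larger pools, pooled ions, 3.5 H⁺/ATP), the methanol rate is
  ceiling-bounded near ~300 by the methanol-methyltransferase capacity and
  the ATP-limited biomass budget. The shipped tables are also internally
  inconsistent: the Mcr allocation implies ~10⁷ complexes per cell against
  the ~10⁴ measured by single-molecule counting. The package reproduces
  the published structure and all ratio/stoichiometry-level observables
  (the 3:1 efflux ratio emerges exactly) but reports absolute rates
  honestly rather than rescaling any stated condition to force agreement.
- **Sensitivity orderings.** The methanol ranking reproduces the published
  top pair (Mcr most sensitive, Mtr second). The acetate ordering differs
  from the published one, for the same structural reason as the absolute
  rates: acetoclastic flux is bottlenecked at the reductase rather than
  distributed across the pathway.
- Growth is quasi-linear once the adenylate pool saturates (the
  first-order cell-mass reaction caps `dM/dt` at `k·[ATP]_max·yield`), so
  the nominal "8 h doubling" applies only to the parameter's definition,
  not to the realised culture curve.
- CO accumulates during acetoclastic growth because the network contains
  no CO-oxidation reaction; this reproduces the published behaviour and is
  not corrected.
- Problem sizes used by the test suite and the acceptance script (400 h
  sensitivity windows, 30 000 h exhaustion cap, 12-cell phantoms, 8-point
  fit curves) were chosen as the smallest sizes at which each quantity is
  well-resolved.
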