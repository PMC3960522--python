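# methanokin

Kinetic modelling and single-cell quantification for the methanogenic
archaeon *Methanosarcina acetivorans*.

*M. acetivorans* reduces one-carbon compounds to methane and is one of the
few organisms that can do so from methanol (methylotrophic pathway), from
acetate (acetoclastic pathway), or from CO. `methanokin` implements, as a
reusable and tested package, a biomass-coupled kinetic model of these
pathways together with the single-cell measurements that parameterise and
validate such models:

- **`network` / `simulate`** — a 27-reaction Michaelis–Menten ODE model of
  methanogenesis (methylotrophic, acetoclastic and electron-transport
  reactions plus ATP synthase and a first-order cell-mass reaction) in a
  1 mL compartment. Each enzyme's concentration is tied to the current
  cell mass through RNA-seq-derived proteome stoichiometries, so growth
  and catalysis feed back on one another.
- **`growth`** — the proteome-allocation arithmetic: RPKM-weighted protein
  mass fractions `a_i = m_i·RPKM_i / Σ_j m_j·RPKM_j` converted to
  micromoles of enzyme per mole of ATP via the protein fraction (0.63) and
  growth yield (15.4 g cell mass per mol ATP).
- **`sensitivity`** — relative (logarithmic) sensitivities
  `s = (x/Y) ∂Y/∂x` of growth observables to enzyme copy numbers, and
  enzyme rankings.
- **`fitcal`** — bounded multi-start least-squares fitting of uncited rate
  constants to substrate-depletion / culture-mass curves, with
  simulate–corrupt–refit recovery experiments.
- **`quantify`** — single-molecule pulldown (SiMPull) arithmetic: spot-count
  calibration, copies-per-cell, and the proteome-mass-fraction estimator.
- **`morpho`** — DIC-microscopy morphometry: Hilbert-transform contrast
  enhancement along the shear axis, threshold-plus-watershed segmentation,
  and prolate-spheroid shape statistics.
- **`synth`** — seed-deterministic generators (RPKM tables, noisy growth
  curves, SiMPull spot counts, DIC-like phantoms) that emit ground truth so
  every stage is testable offline.

## The model

Reactions follow three irreversible mechanisms: unimolecular
Michaelis–Menten `v = k_cat·E·s/(K_M+s)`, bimolecular Michaelis–Menten with
a shared `k_cat`/`K_M` taken as the product of saturation factors, and
first order `v = k·s`. Reactions with more than two reactants apply the
bimolecular law to their two designated substrates while the remaining
co-reactants are converted at the same flux (a constant-flux side
reaction). The cell-mass reaction `ATP → ADP + Pi + biomass` runs at
`0.125 h⁻¹·[ATP]` and deposits 15.4 g of biomass per mole of ATP; 63% of
biomass is protein, apportioned over the methanogenic enzymes by the
packaged allocation tables (methanol- and acetate-grown columns), so
enzyme concentrations are an algebraic function of the growing cell mass.

The packaged parameter and allocation tables
(`src/methanokin/data/table1.tsv`, `table2_*.tsv`) transcribe the published
model; see `docs/methods.md` for the assumptions, units, and the known
quantitative limitations of that parameterisation.

## Worked example

```python
import methanokin as mk

tc = mk.run(mk.Scenario(duration_h=400.0, sample_h=0.5))  # 125 mM methanol
print(tc.cell_mass_mg[-1])      # 0.2647  mg of cells after 400 h
print(tc.methane_rate())        # 0.0332  peak CH4 rate, nmol/mL/min
print(tc.efflux_ratio())        # 2.956   cumulative CH4:CO2 so far

from methanokin.quantify import copies_per_cell
est = copies_per_cell(5.0, 3e8, cells_sd_per_ml=1e8)
print(est.copies, est.copies_sd)   # 10038.3 +/- 3346  ribosomes per cell

from methanokin.morpho import ellipsoid_volume_fl
print(ellipsoid_volume_fl(2.9, 2.3))   # 8.03 fL methanol-grown cell volume
```

The first block integrates methanol growth under the study conditions
(0.1 mg inoculum, ATP/ADP/Pi = 10/1/10 mM, 0.009 mM carrier pools): the
culture converts its starting ATP pool into biomass and then grows slowly
at the rate the methanogenesis flux can regenerate ATP, with the
cumulative CH4:CO2 ratio approaching the stoichiometric 3:1 of
methylotrophic disproportionation (4 CH3OH → 3 CH4 + CO2). The
copies-per-cell call reproduces a published SiMPull table row with its
uncertainty propagated in quadrature; the volume call is the
prolate-spheroid volume (π/6)·L·W² of a cell with the mean measured
methanol-grown dimensions.

From a shell the same pipelines are available as `methanokin simulate`,
`methanokin sensitivity`, `methanokin quantify copies|calibration`, and
`methanokin morpho`.

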