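# Methods

This note records the model, its numerical treatment, the parameter
choices, and the design decisions that were genuinely open, in the order a
user meets them: assay quantification → rate laws → transport solve →
post-processing → synthetic data.

## Assay quantification

One culture well holds a minced tissue piece (region NP, AF, or CEP) in
V_media of media (0.6 mL for NP, 0.8 mL for AF/CEP) with hourly glucose and
lactate readings over 0–5 h. Tissue volume uses Archimedes' principle with
ρ_PBS = 1.07 g/cm³; cell number is ρ_cell·V_tissue with regional densities
(NP 35.71, AF 53.57, CEP 78.57 million cells/mL) from rat-disc histology.
Rates are Δc·V_media/(Δt·ρ_cell·V_tissue), reported in nmol/million
cells/h (mM ≡ µmol/mL, ×1000 to nmol).

Steady-state rates average the hourly interval rates whose *both*
endpoints lie in the [2, 5] h window — three intervals for hourly sampling
— so the 1→2 h interval is excluded. This is a deliberate reading of
"averaged from 2 to 5 h"; a regression-slope alternative over the same
window is exposed (`method="regression"`) and coincides with the interval
mean for exactly linear series. Per-animal aggregation takes arithmetic
means of GCR, LPR, and of the per-well LPR:GCR ratios (mean of ratios, not
ratio of means). Wells with non-positive averaged GCR carry an undefined
(NaN) ratio rather than a fabricated one.

Known limitation: buoyant weight is measured after culture, and no
correction is applied for any mass change during culture.

## Rate laws and oxygen coupling

Glucose consumption and lactate production both follow Michaelis–Menten
kinetics *in glucose*: Q_glu = −ρ_cell·Vg·c_glu/(Kg + c_glu),
Q_lac = +ρ_cell·Vl·c_glu/(Kl + c_glu). The packaged parameter file
(`src/ivdmet/data/rat_disc_kinetics.yaml`) carries (Vmax, Km) per region at the 1% and
5% oxygen anchors, for untreated and 10%-CSE-exposed tissue (CSE rescales
Vmax only; Km is shared), together with cell densities and solute
diffusivities. The single unit conversion — nmol/Mcells/h × Mcells/mL →
mM/s, divisor 3.6 × 10⁶ — lives in `units.py`.

Oxygen consumption and ATP synthesis follow the glycolysis/oxidative-
phosphorylation stoichiometry: Q_O2 = 3·Q_lac + 6·Q_glu, zeroed when
lactate production exceeds twice glucose consumption (pure glycolysis), and
Q_ATP = −2·Q_glu − 6·Q_O2, i.e. 2 ATP per glucose on the glycolytic floor
and up to 38 with full oxidation.

### Oxygen interpolation and the sub-anchor closure

Between the anchors (0.011 and 0.054 mM dissolved oxygen, the printed
roundings of 0.01 and 0.05 atm through H = 929.6 atm/M) all four kinetic
parameters vary linearly in local oxygen concentration; above 0.054 mM they
clamp to the 5% set. Below the 1% anchor the data say nothing, and the
choice matters enormously because the NP and AF interiors sit far below it.
Four closures are implemented (`mode=` on `interpolate_params`,
`reaction_rates`, `solve_steady_state`):

- **`vmax_to_origin` (default).** The Vmax interpolation table is extended
  through the origin: below the anchor every Vmax scales as c_O2/c(1%), Km
  holds its 1% value. The oxygen sink then vanishes *linearly* in oxygen,
  so the steady-state oxygen field is strictly positive with no extra
  regularisation, the hypoxic minimum lands on the µM scale, and the
  regional oxygen-availability ordering CEP > AF > NP emerges. This is the
  only implemented closure whose steady states reproduce the qualitative
  structure expected of the tissue (a hypoxic-but-viable NP core); it also
  reflects the biology that metabolic capacity, not substrate affinity, is
  what collapses as oxygen vanishes.
- **`glycolytic`.** Vmax continues the anchor line toward c_O2 = 0 with Km
  clamped; the NP lactate:glucose ratio then approaches the glycolytic
  ceiling of 2 and the NP sink shuts off near ~1 µM, but the AF ratio stays
  near 1.6 and the AF oxygen field collapses to the regularisation scale.
- **`extrapolate_to_zero`.** All four parameters continue the anchor line
  (floored at a small positive epsilon). The residual oxygen sink persists
  to c_O2 = 0 (NP ratio reaches only ~1.94) and oxygen collapses to the
  regularisation scale wherever the tissue is thick.
- **`clamp`.** Hold the 1% set; the strongest residual sink, same collapse.

Independently of the mode, Q_O2 is multiplied by the availability factor
c_O2/(c_O2 + ε), ε = 1 × 10⁻⁴ mM. In the extrapolation modes this factor is
what guarantees positivity; under the default closure it is a mild
correction (≤ 5% above 2 µM). Q_ATP uses the regularised Q_O2, so the
energy bookkeeping is consistent with the oxygen actually consumed.

### Michaelis–Menten fitting

`fit_michaelis_menten` is a bounded least-squares fit (scipy
`curve_fit`, Vmax ≥ 0, 0 < Km ≤ 10³ mM) seeded at (max rate, median
concentration). Three noiseless design points at {1.5, 5.5, 25} mM identify
any (Vmax, Km) over the physiological grid to better than 10⁻⁶ relative
(property-tested). Degeneracies are flagged, not hidden: all-zero rates
return Vmax = 0 with Km = NaN (`km_indeterminate`); data confined to the
linear regime (fitted Km far above the sampled range, or at the bound)
set `km_at_bound`.

## Transport model

Geometry: cylinder R = 1.5 mm, H = 1 mm; CEP occupies the full-radius slabs
within 0.2 mm of either face; between them the NP core (r < 0.85 mm) is
wrapped by the AF ring. The full-radius CEP reading means the entire
superior/inferior faces are CEP–media interfaces, consistent with all
exposed surfaces (AF periphery, both CEP faces) carrying fixed media
concentrations. Closed-form region volumes: CEP 2.8274, NP 1.3618,
AF 2.8793 mm³ (total 7.0686 mm³).

Discretisation: uniform cell-centred finite volumes on the axisymmetric
(r, z) half-plane (the geometry, boundary data, and kinetics are all
axisymmetric, so nothing is lost relative to a 3D mesh; this is verified by
mesh-convergence testing rather than node-count matching). Cell volumes are
2πr·Δr·Δz and sum to πR²H exactly. Face conductances use harmonic-mean
diffusivities, so flux is continuous across region interfaces with
piecewise-constant D; the r = 0 axis is a natural zero-flux face; Dirichlet
boundaries enter through half-cell conductances. The grid must resolve the
regional features (≥ 4 cells across the CEP thickness and the NP radius).

Nonlinear solve: damped Picard (successive substitution). Each outer step
interpolates the kinetic parameters at the current oxygen field, linearises
the glucose and oxygen sinks implicitly — Q = −k(c_prev)·c with
k = ρVg/(Kg + c_prev)/3.6e6 for glucose and k = |Q_O2(prev)|/(c_prev + ε)
for oxygen — and re-solves the two sparse linear systems (SuperLU).
Implicit sinks keep the operator an M-matrix, so every iterate obeys
positivity and the discrete maximum principle. Iterates are under-relaxed
with damping 0.5; convergence is max field change per iteration relative to
the boundary concentration, tolerance 10⁻⁸, cap 500 iterations (the preset
scenarios converge in 24–39). Lactate is a pure source problem and is
solved once from the converged glucose/oxygen fields; Q_ATP is evaluated
pointwise. There is no randomness anywhere in the solve.

Internal units are mm, s, mM (diffusivities ×10⁶ from m²/s); ATP synthesis
is reported in µM/s.

Verification: zero-source solves return the boundary value exactly; a wide
flat cylinder reproduces the axial slab deficit Q·L²/8D and a tall one the
radial deficit Q·R²/4D to < 1%; discrete source/boundary-flux balance holds
to 10⁻⁸ (linear) and 10⁻⁶ (converged coupled solve); the fixed point is
invariant to halving the damping factor; and field extrema move < 2% under
grid halving at the reporting resolution.

### Reporting convention for extrema

Headline extrema (min glucose, max lactate, min oxygen, max ATP) are taken
over interior cell-centre values on the 240 × 160 reporting grid; boundary
faces sit at the prescribed media values by construction and are not model
predictions. Note the ATP field attains its supremum *at* the exposed
boundary (the best-fed tissue), so a reported "maximum ATP synthesis rate"
is intrinsically tied to the sampling locus: cell centres ~3 µm from the
boundary read within ~1% of the boundary-concentration rate, whereas any
coarser sampling reads lower, because oxygen (and with it the interpolated
Vmax) falls steeply over the first ~0.1 mm. Comparisons between solvers
with different meshes can therefore differ by ~10–15% in this quantity
while agreeing everywhere else.

## Scenario post-processing

`summarize` produces volume-weighted min/max/mean/integral per region and
overall; integrals are additive across regions by construction.
`normalize` expresses availability as fractions of saturation under the
reference (physiological) scenario: solute fraction =
∫c dV / (c0,ref × V_region) — so lactate, which accumulates above its
boundary value, may exceed 1 — and ATP fraction =
∫Q_ATP dV / (max Q_ATP,ref × V_region). The ATP reference maximum is global
by default; a per-region variant is exposed (`atp_reference="per_region"`).
`compare_table` flattens the headline extrema to one row per
(scenario, quantity) with unit-suffixed values.

## Synthetic data

The cohort generator emulates the assay design: per animal × region ×
treatment × replicate, a tissue mass is drawn uniformly, the buoyant weight
is back-computed from an assumed tissue density of 1.10 g/cm³
(generator-internal; the estimator consumes the emitted weights), the cell
count follows from regional density, and concentration trajectories are
integrated under constant true rates before i.i.d. Gaussian noise
(default SD 0.02 mM — a free generator parameter, not an instrument
specification)
is added to every reading. Default true rates are centred on measured
rat-disc condition means (e.g. NP control 149.13/195.30, AF 80.57/94.89,
CEP 40.23/54.65 nmol/million cells/h); ground truths violating the
glycolytic ceiling (LPR > 2·GCR) are rejected. Everything is deterministic
under the design seed.

Designs whose noiseless trajectories would drive media glucose below the
0.5 mM viability floor are refused. Because constant-rate trajectories
overstate late-interval consumption relative to saturating kinetics, the
default tissue mass range is 50–70 mg (within the assay's nominal 50–100 mg
band): at 1.5 mM media glucose the most active NP wells would cross the
floor above ~71 mg. Users modelling heavier pieces can widen the range and
drop the low-nutrient arm.

What passing tests on synthetic data do and do not show: the generator has
constant rates, additive i.i.d. noise, and no within-well nutrient
gradients, so round-trip recovery demonstrates the estimator's correctness
and noise propagation — not robustness to rate drift, autocorrelated
analyzer error, or depletion effects in real wells.

## Known limitations

- The sub-1%-oxygen closure is an extrapolation beyond the fitted data;
  all four variants are exposed precisely because no measurement
  constrains them.
- Steady state only; no transient dynamics, no mechanical deformation or
  poroelastic coupling, no pH/lactate feedback on the kinetics.
- Cell density (hence viability) is held constant across treatments when
  computing volumetric rates, which is what makes the four scenarios
  comparable but ignores treatment-induced cell loss.
- The CSE parameter set rescales Vmax only; any CSE effect on Km is
  unmodelled.
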