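# ivdmet

Nutrient transport and cell energy metabolism of the intervertebral disc
(IVD), built around a rat lumbar-disc tissue model. The package is aimed at
disc mechanobiology and nutrition researchers who need to (1) turn explant
culture measurements into normalised cellular metabolic rates, (2) fit
Michaelis–Menten rate laws to those measurements, and (3) predict the
steady-state glucose / oxygen / lactate environment and ATP synthesis inside
the disc under physiological, cigarette-smoke-extract (CSE), low-nutrient,
and combined conditions.

## The science

**Explant assay.** Minced tissue from the three disc regions — nucleus
pulposus (NP), annulus fibrosus (AF), cartilaginous endplate (CEP) — is
cultured in a known media volume and glucose/lactate concentrations are read
hourly. Tissue volume follows from Archimedes' principle,
V_tissue = (W_wet − W_PBS)/ρ_PBS, and rates are

    GCR or LPR = Δc · V_media / (Δt · ρ_cell · V_tissue)

in nmol per million cells per hour (glucose consumption positive for falling
glucose, lactate production positive for rising lactate). Steady-state rates
average the hourly interval rates in the 2–5 h window; replicate wells are
averaged within each animal. The LPR:GCR ratio indexes reliance on
glycolysis, with 2 lactate per glucose as the pure-glycolysis ceiling.

**Kinetics.** Rates saturate in glucose, rate = Vmax·c/(Km + c), with
(Vmax, Km) fitted per region at two dissolved-oxygen anchors (1% and 5%
atmospheric partial pressure; 0.011 and 0.054 mM via Henry's law,
H = 929.6 atm/M) and interpolated linearly in local oxygen concentration.
CSE exposure substitutes a reduced Vmax set (shared Km). Oxygen consumption
and ATP synthesis couple stoichiometrically to the glucose/lactate rates:

    Q_O2  = 3·Q_lac + 6·Q_glu   (0 when Q_lac > −2·Q_glu)
    Q_ATP = −2·Q_glu − 6·Q_O2

**Transport model.** The disc is idealised as a cylinder (R = 1.5 mm,
H = 1 mm; NP core radius 0.85 mm; CEP slabs 0.2 mm at both faces) with
fixed media concentrations on all exposed surfaces. Each solute satisfies
steady-state diffusion with a metabolic source, −∇·(D∇c) = Q, discretised
by a cell-centred finite-volume scheme on an axisymmetric (r, z) grid and
solved by damped Picard iteration with implicitly linearised sinks (which
preserves positivity and the maximum principle). The ATP synthesis field is
evaluated pointwise from the converged concentrations.

## Worked example

```python
import ivdmet as m
from ivdmet.report import headline

params = m.load_reference_kinetics()          # packaged per-region parameters
grid = m.build_grid(m.DiscGeometry(), 240, 160)
sol = m.solve_steady_state(grid, m.PRESET_SCENARIOS["physiological"], params)
print(headline(sol, grid))
```

prints (39 Picard iterations, residual 7.5e-09):

```
{'scenario': 'physiological', 'min_glucose_mM': 5.418,
 'max_lactate_mM': 0.989, 'min_oxygen_uM': 2.01,
 'max_atp_uM_per_s': 18.98}
```

Reading: with physiological media (5.5 mM glucose, 5% oxygen, 0.9 mM
lactate) the disc interior depletes glucose only slightly (5.42 mM
minimum), accumulates lactate modestly above the media value, and drives
the NP core to ~2 µM oxygen — hypoxic but strictly positive — while ATP
synthesis peaks near the well-fed AF periphery. Re-running with the `"cse"`
preset conserves oxygen (minimum rises to 7.0 µM) but cuts peak ATP
synthesis roughly in half — smoke exposure pushes the tissue into a
low-yield glycolytic state.

The same pipeline is scriptable from a shell:

```bash
ivdmet simulate-cohort --seed 5 --out-dir work/      # synthetic assay data
ivdmet quantify --measurements work/measurements.csv --wells work/wells.csv \
    --out work/rates.csv
ivdmet run-scenario --preset cse --out-dir work/     # fields + summaries
```

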