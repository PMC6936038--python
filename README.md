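# homeostat

Homeostatic-ensemble mechanics of single adherent cells, with free-energy
based forecasting of human mesenchymal stem cell (hMSC) lineage commitment.

## The problem

Within a day or two of seeding, hMSCs commit to a lineage — osteoblast,
myoblast, adipocyte, or none — steered by mechanical and geometric cues:
substrate stiffness, the size of adhesive islands, or contractility-reducing
drugs (ROCK inhibitors). Individual cell shapes fluctuate too much for any
single morphometric to predict fate. `homeostat` implements a statistical
cell-mechanics model in which the *distribution* of morphologies, and the
cytoskeletal free energy it implies, carries the forecast.

## The model

A cell is an open system in a nutrient bath. Over interphase it holds its
average molecular content fixed, which pins the ensemble-average Gibbs free
energy of the cell–substrate system to that of a suspended cell:
⟨Ĝ⟩ = G_S. The maximum-entropy distribution over morphological microstates
j subject to that constraint is

    P_eq(j) = Z⁻¹ exp(−ζ Ĝ(j)),        ⟨Ĝ⟩ = G_S,

where 1/ζ is the homeostatic temperature. Each microstate is a smooth planar
deformation of a circular reference cell with

    Ĝ = F̂passive + F̂cyto + F̂sub

— a compressible 2D Ogden body (cytoplasm + stiffer nucleus), an active
stress-fibre cytoskeleton (bound contractile fibres in Langmuir-type
chemical equilibrium with a uniform unbound protein pool), and the elastic
energy the cell's tractions store in the substrate. The package samples
P_eq by Metropolis Monte Carlo, solving ζ per environment.

Lineage forecasting: over the 24–48 h commitment window the cell visits Nc
decorrelated microstates, so the time-averaged cytoskeletal free energy
F̄cyto is Gaussian with mean µ and variance σ²/Nc, with (µ, σ) the
homeostatic moments of F̂cyto. A cell commits to lineage x when F̄cyto falls
in a band F̄x ± ΔF̄x:

    Px = Φ((F̄x+ΔF̄x−µ)√Nc/σ) − Φ((F̄x−ΔF̄x−µ)√Nc/σ),
    P̃x = Px / Z_L,   Z_L = max(1, Σx Px),

with 1 − ΣP̃x remaining undifferentiated. Bands are media-specific and are
calibrated on one cue family (e.g. a stiffness sweep), then used to predict
another (e.g. island sizes). See `docs/methods.md` for closures, parameters
and limitations.

## Worked example

```python
from homeostat import CellParameters, elastic, with_suspension
from homeostat.forecast import calibrate_bands, forecast
from homeostat.sampler import sample_homeostatic_ensemble
from homeostat.experiments import GROWTH_CALIBRATION_FRACTIONS

params = with_suspension(CellParameters())
print(f"suspension energy G_S = {params.G_S:.3f}")

ens = {}
for E in (10.0, 30.0, 70.0):        # substrate stiffness, kPa
    ens[E] = sample_homeostatic_ensemble(elastic(E), params, seed=7,
                                         production_steps=20_000)
    s = ens[E].samples
    print(f"E_sub={E:>4.0f} kPa: zeta={ens[E].zeta:.2f}  "
          f"A^={s['A_hat'].mean():.2f}  N^b={s['N_b'].mean():.2f}  "
          f"F^cyto={s['F_cyto'].mean():.2f} +/- {s['F_cyto'].std():.2f}")

moments = {E: (float(e.samples['F_cyto'].mean()),
               float(e.samples['F_cyto'].std(ddof=1))) for E, e in ens.items()}
cal = calibrate_bands(moments, {E: GROWTH_CALIBRATION_FRACTIONS[E] for E in ens},
                      Nc=15, media="growth")
fc = forecast(ens[30.0], cal.media_model)
print("forecast at 30 kPa (growth media):")
for lin, p in sorted(fc.probabilities.items()):
    print(f"  P_{lin} = {p:.2f}")
print(f"  undifferentiated = {fc.undifferentiated:.2f}")
```

Output:

```
suspension energy G_S = 7.131
E_sub=  10 kPa: zeta=3.82  A^=1.15  N^b=0.68  F^cyto=4.54 +/- 0.39
E_sub=  30 kPa: zeta=2.11  A^=1.26  N^b=0.83  F^cyto=2.96 +/- 0.71
E_sub=  70 kPa: zeta=1.79  A^=1.29  N^b=0.87  F^cyto=2.30 +/- 0.77
forecast at 30 kPa (growth media):
  P_myoblast = 0.00
  P_osteoblast = 0.80
  undifferentiated = 0.20
```

Reading it: stiffer substrates let the cell spread (normalized area Â up),
polymerize more stress fibres (N̂b up) and lower its cytoskeletal free
energy F̂cyto, while ζ adjusts per environment so every ensemble's mean Ĝ
equals G_S. After calibrating the growth-media bands on the sweep, the
30 kPa forecast is osteoblast-dominated with about 20% of cells left
undifferentiated — the osteogenic-optimum behaviour the band classifier is
built to capture.

## Command line

```bash
homeostat sample --stiffness-kpa 30 --steps 200000 --seed 1 --out ens.csv
homeostat observables ens.csv
homeostat forecast ens.csv --media-config growth.yaml
homeostat sweep-stiffness --outdir results/
homeostat sweep-island --media mixed --outdir results/
homeostat rock --outdir results/
homeostat render ens.csv --index 0 --stiffness-kpa 30 --out cell.png
```

Sweeps write per-condition CSV tables (stiffness or island area vs lineage
fractions, F̂cyto moments, observable means/IQRs) and PNG figures
regenerated from those CSVs; `rock` runs the paired σmax 240 → 231 kPa
inhibition comparison on a 2725 µm² island.

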