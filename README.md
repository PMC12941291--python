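# migrisk

Packaging–food–digestion exposure modelling for polymer packaging
additives: finite-bath Fickian migration kinetics, in vitro digestion
bioaccessibility, and bioaccessibility-adjusted dietary risk screening.

## Who this is for

Food-safety and food-contact-material researchers who need to go from a
migration experiment (a polymer film in contact with a real food or
simulant at a controlled surface-to-volume ratio) to a defensible dietary
exposure estimate. The package chains three stages, each usable on its own:

1. **Migration kinetics** — an additive initially uniform in a film of
   thickness *L* (zero-flux back face) diffuses with coefficient *D* into
   a finite, well-stirred food phase. With the polymer/food partition
   coefficient *K*<sub>P/F</sub> = *C*<sub>P,∞</sub>/*C*<sub>F,∞</sub> and the
   dimensionless food-phase capacity α = *V*<sub>F</sub>/(*K*<sub>P/F</sub>·*V*<sub>P</sub>),
   the transferred fraction follows the classical limited-volume sorption
   series

   *M*<sub>F,t</sub>/*M*<sub>F,∞</sub> = 1 − Σₙ [2α(1+α)/(1+α+α²qₙ²)] · exp(−D·t·qₙ²/L²),

   where qₙ is the n-th positive root of tan q = −α·q. The observable
   migration ratio is MR(t)% = 100 · α/(1+α) · *M*<sub>F,t</sub>/*M*<sub>F,∞</sub>.
   The package solves the root equation, evaluates the series, verifies it
   against an independent finite-volume PDE solver, and estimates (*D*, α)
   from observed curves by bounded least squares.

2. **Bioaccessibility** — from simulated-digestion measurements,
   BA(%) = 100·(C_d·V_d)/(C_s·V_s), with procedural-blank correction of
   the digest concentrations.

3. **Risk** — estimated daily intake
   EDI = V · C_p · (MR_f/100) · m_p · 10³ / BW · (BA/100) (ng/kg bw/day)
   and hazard quotient HQ = EDI/RfD, screened against HQ < 1.

The packaged reference tables cover five organophosphate flame retardants
(TPhP, EHDPP, TBOEP, TnBP, TPPO) migrating from polypropylene into nine
foods, with their fitted kinetic parameters, reference doses and printed
exposure results; a synthetic-data module regenerates the whole study
design (triplicate curves over 0.5–72 h, spiked-food digestion with blank
contamination) with known ground truth.

## Worked example

```python
from migrisk import (ContactSystem, migration_curve_model, fit_diffusion,
                     edi_from_migration, hazard_quotient, PackagingAssumption)

system = ContactSystem()              # 80 µm film, 9 cm², 15 mL food = 6 dm²/L
curve = migration_curve_model(8.00e-11, 0.328, system.film.thickness_cm,
                              (0.5, 1, 2, 4, 6, 24, 48, 72),
                              compound="TPhP", food="Eastern leaf")
print([round(v, 2) for v in curve.mr_percent])
# [4.73, 6.38, 8.46, 10.97, 12.62, 18.79, 21.75, 23.17]

fit = fit_diffusion(curve, system, mode="co_fit_alpha")
print(f"D = {fit.d_cm2_s:.3e} cm2/s, alpha = {fit.alpha:.3f}, R2 = {fit.r_squared:.5f}")
# D = 8.000e-11 cm2/s, alpha = 0.328, R2 = 1.00000

mr_f = curve.mr_percent[-1]           # final migration ratio at 72 h
edi = edi_from_migration(0.363, PackagingAssumption(), mr_f, ba_percent=17.3)
print(f"EDI = {edi:.1f} ng/kg bw/day, HQ = {hazard_quotient(edi, 70_000):.2e}")
# EDI = 97.0 ng/kg bw/day, HQ = 1.39e-03
```

The curve rises steeply early (diffusion-limited), approaches its
equilibrium plateau 100·α/(1+α) = 24.7 %, and refitting recovers the
generating *D* exactly. Scaling by packaging content (100 µg/g), packaging
mass per kg food (4 g/kg), daily consumption (0.363 kg/day), body weight
(60 kg) and a 17.3 % bioaccessible fraction gives a daily intake five
hundred times below the 70,000 ng/kg bw/day reference dose (HQ ≈ 1.4×10⁻³):
acceptable risk.

## Command-line pipeline

```sh
migrisk simulate --out run/ --seed 1 --cv 0.05   # synthetic study design
migrisk fit      --curves run/migration_curves.csv --out run/fits.csv
migrisk ba       --digestion run/digestion.csv --blanks run/blanks.csv --out run/ba.csv
migrisk risk     --fits run/fits.csv --ba run/ba.csv --out run/risk.csv
migrisk reproduce-paper --out run/repro          # pass/fail anchor table
```

Every stage writes a manifest (config echo, seed, version) so
deterministic runs reproduce bit-for-bit.

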