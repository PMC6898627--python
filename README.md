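# mucoperm

Compartmental simulation of *in vitro* dissolution testing for respirable-size
(1–5 µm) dry-powder drug particles: dissolution in a thin (~50 µm) film of
mucus simulant spread over a dialysis membrane, permeation across the
membrane into a perfused receiver, and continuous collection of the perfusate.

The package is aimed at inhalation-biopharmaceutics scientists who run (or
design) small-volume dissolution/permeation assays and want a mechanistic
model to predict which parameters — drug solubility, intrinsic dissolution
rate, particle size, film volume, membrane thickness, perfusate flow —
control the observed permeation profile before going to the bench.

## Model

Drug mass moves through four stocks,

```
solid particles → dissolved in mucus film → receiver (perfusate) → collection tube
```

with rates

- **Dissolution** (Noyes–Whitney, monodisperse shrinking spheres):
  dM/dt = k S_t (C_s − C), with rate constant k = IDR / C_s, total powder
  surface area S_t = 6 M₀ d_t² / (d₀³ ρ) and particle diameter
  d_t = (M_t d₀³ / M₀)^⅓. The driving force is clamped at zero at
  saturation (no precipitation is modelled).
- **Permeation**: P S (C_mucus − C_perfusate). Under a *well-stirred* donor
  the permeability is constant, P = P_exp h_exp / h_m. Under an *unstirred*
  donor a drug-depleted layer h_d = f_d h_t grows next to the membrane
  (f_d = fraction of the dose that has left the film, h_t = V_d/S the film
  thickness), adding series resistance: P_t = P_exp h_exp / (h_m + f_d h_t).
- **Collection**: C_perfusate × Q, a well-mixed constant-volume receiver
  swept at flow rate Q.

The system is integrated with a fixed-step scheme (classical RK4 by default,
forward Euler selectable) with per-step flux limiting so no stock goes
negative and the mass balance stays exact. Doses can be deposited as solid
particles or pre-dissolved solution. A companion estimator recovers the
permeability coefficient from donor-decay data via the ln-linear relation
ln C_d = ln C_d0 − (P S / V_d) t.

Two shipped presets hold the bench parameters of the reference apparatus
(4.91 cm² membrane, 25 µL film, 500 µL receiver, 0.4 mL/min flow) for two
anti-tubercular drugs of contrasting solubility: moxifloxacin
(C_s = 17.70 mg/mL) and ethionamide (C_s = 0.46 mg/mL).

## Worked example

```python
from mucoperm import DissolutionPermeationModel

res = DissolutionPermeationModel.from_preset("ethionamide_table1").simulate()
print(res.summary())
```

```
Dissolution–permeation simulation
=================================================
drug:            ethionamide
dose:            50 ug (particles)
stirring:        well_stirred
integrator:      rk4 (dt = 0.01 min)
horizon:         120.0 min
mucus film:      25 uL over 4.91 cm2 (50.9 um)
-------------------------------------------------
final % collected:     100.00
time to   50% collected: 23.3 min
time to   90% collected: 44.0 min
time to   99% collected: 66.3 min
peak donor conc:       0.447 mg/mL
```

The peak donor concentration sits at the 0.46 mg/mL solubility: a 50 µg dose
exceeds the 11.5 µg the 25 µL film can dissolve, so the film stays saturated
while excess solid remains and dissolution — not membrane diffusion — limits
the early permeation. Comparing with the same dose pre-dissolved:

```python
sol = DissolutionPermeationModel.from_preset(
    "ethionamide_table1", dose_form="solution").simulate()
```

```
particles, % collected at 30/60/120 min: [64.9, 98.1, 100.0]
solution,  % collected at 30/60/120 min: [94.8, 99.8, 100.0]
```

The suspension lags the solution by ~30% of the dose at 30 min — the
signature of dissolution-limited delivery for a poorly soluble drug. Running
the same comparison for moxifloxacin gives profiles that differ by less than
1% of the dose at every time: its particles dissolve essentially instantly
and membrane diffusion controls everything.

The same scenarios are available from the shell:

```bash
mucoperm simulate --preset ethionamide_table1 --form particles --out run.csv
mucoperm sweep --preset ethionamide_table1 --parameter mucus_volume \
    --values 25,50,100 --out sweep.csv
mucoperm fixture --pexp 5.3e-4 --sigma 0.02 --seed 1 --out decay.csv
mucoperm fit --csv decay.csv
```

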