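# graywhale-sdp

State-dependent life-history modeling of pregnant western gray whales
(*Eschrichtius robustus*) on the Sakhalin Island feeding grounds, built to
ask a population-consequences-of-disturbance (PCoD) question: do seismic
surveys near the feeding areas, through lost foraging and displacement,
measurably lower reproductive success?

Pregnant gray whales are capital breeders: a calf is paid for with fat
accumulated during a single ~25-week foraging season.  The package couples

1. **a stochastic dynamic program (SDP)** — backward iteration over a
   discretized state space (fat mass *F*, fetal length *G*, location among
   11 feeding cells, current prey category) that computes the expected
   terminal reproductive fitness
   *V(t, F, G, cell, k)* and the probability of each of four daily
   behaviors (leave the feeding ground, feed here, travel within the cell,
   travel to another cell);
2. **a forward Monte-Carlo simulation** of replicate populations following
   those behavior probabilities in 6-h steps, with an optional acoustic
   disturbance layer: in any 6-h bin, a whale in a cell with exposure
   probability *p*(cell, bin) of receiving >= 163 dB re 1 µPa² SPL responds
   by relocating to the nearest undisturbed cell and losing that foraging
   opportunity;
3. **the field-data comparison statistics** — zero-inflated beta regression
   for the daily proportion of pregnant females seen nearshore, per-cell
   hurdle-gamma regressions for scan-survey densities, a binomial-logit
   model of the pregnant fraction, block-to-cell density aggregation
   (D_ik = Σ_j D_ijk·A_ijk / Σ_j A_ijk), Cohen's *d* with the usual
   0.2 / 0.5 / 0.8 cutoffs, and reproductive-rate bookkeeping under a
   minimum two-year inter-birth interval;
4. **seeded synthetic-data generators** for every input stream (prey
   samples, acoustic block grids, photo-identification days, scan surveys,
   calving roster), each the measurable inverse of its fitting stage, so
   the whole pipeline runs and is testable with no field data.

Terminal fitness is the product of overwinter maternal survival (logistic
in departure fat / mass), calf survival by maternal fat (logistic on the
metabolic scale fat / M^0.75, with a variant-specific asymptote) and calf
survival by fetal length (a scaled logistic that is exactly zero with no
fetus).  Three variants (low / medium / high) and four minimum maternal
lengths L_min ∈ {11.0, 12.1, 12.7, 13.0} m form the 3 × 4 factorial of
model permutations.  See `docs/methods.md` for the full model account.

## Worked example

```python
import graywhale_sdp as g
from graywhale_sdp.workbench import Inputs, Scenario, run_scenario

scenario = Scenario(fitness_variant="medium", L_min=12.7,
                    n_fat=40, n_fetal=20, n_lengths=5,
                    n_replicates=10, population_size=50, seed=1)
bundle = run_scenario(scenario, Inputs())          # backward + forward
rep = bundle["reproduction"]
print(f"P(successful reproduction) = {rep.mean:.3f} +/- {rep.sd:.3f}")
occ = bundle["occupancy"]
for w in (4, 8, 16, 24):
    near = occ.weekly_area[:, w, 0].mean()
    off = occ.weekly_area[:, w, 1].mean()
    print(f"week {w:2d}: nearshore {near:.3f}  offshore {off:.3f}")
```

prints

```
P(successful reproduction) = 0.248 +/- 0.053
week  4: nearshore 0.000  offshore 0.557
week  8: nearshore 0.000  offshore 0.998
week 16: nearshore 0.000  offshore 0.996
week 24: nearshore 0.000  offshore 0.996
```

Under the medium fitness function a 12.7-m-plus population migrates
offshore essentially on arrival (week 4–5 is the arrival window; the
`outside` balance is whales not yet arrived) and roughly a quarter of
females carry a calf through the following winter.  The observed-rate
arithmetic is one call:

```python
g.reproductive_rate(27, 11, 14)   # 0.875 -> reported as 0.88
```

## Command line

`graywhale-sdp synth|fit-prey|backward|exposure|simulate|fit-field|compare|grid`
wrap the same library calls for shell use; `synth --out DIR` writes a
complete synthetic scenario directory (CSV + YAML).

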