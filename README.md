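# otolife

Otolith-based reconstruction of sardine early life histories: growth,
metabolism, temperature, and survival.

## The problem

Sardine populations in western boundary currents (the Japanese sardine
of the Kuroshio-Oyashio system) and eastern boundary currents (the
Pacific sardine of the California Current) boom and bust on decadal
scales — but in *opposite* temperature regimes. Testing mechanisms for
that contrast requires knowing, fish by fish, the temperatures a
survivor experienced during its larval and juvenile months, how fast it
grew, and how hard its metabolism was working. All three are written
into the otolith, the aragonite ear stone that accretes daily growth
increments and records ambient chemistry.

`otolife` implements that reconstruction as a tested Python library for
fisheries ecologists and sclerochronologists:

- **Growth** — otolith radius at age from daily increment widths, and
  standard length at age by the biological intercept method
  `SL_n = (SL_catch − SL_first)·(OR_n − OR_first)/(OR_catch − OR_first) + SL_first`,
  with Monte Carlo propagation of the 3.8–6.5 mm initial-size
  uncertainty.
- **Metabolism** — the field-metabolic proxy M_oto, the fraction of
  metabolically derived carbon in otolith carbonate, from the δ13C
  mixing model `M_oto = (δ13C_oto − δ13C_DIC)/(δ13C_diet − δ13C_DIC) + ε`
  with Monte Carlo uncertainty over the regional diet/DIC ranges.
- **Temperature** — otolith δ18O inverted through
  `δ18O_oto = δ18O_sw − 0.18·T + 2.69`, either at fixed seawater δ18O
  (California mode, −0.32 ‰) or via monthly quadratic thermometers
  fitted to hydrographic T/S observations (Kuroshio-Oyashio mode).
- **Optimal temperature** — per life stage, the 95th/5th-percentile
  envelopes of M_oto across 1 °C temperature bins (quadratic upper fit,
  log-link lower fit); the gap is an aerobic-scope analogue and its
  argmax the metabolically optimal temperature.
- **Survival** — log recruitment residuals of a Ricker
  stock-recruitment fit, `LNRR_t = ln(R_t/S_t) − (a + b·S_t)`,
  correlated against temperature anomalies; plus Pearson tests,
  AIC-based quadratic-term selection and Benjamini-Hochberg FDR control
  for temperature–growth relationships.
- **Synthetic data** — a generator that runs every forward model in the
  generative direction with known ground truth, so the whole pipeline
  is verifiable without archived otolith material.

## Worked example

Estimate a cohort's metabolically optimal temperature from simulated
otoliths (`examples/optimal_temperature.py`):

```python
from otolife import (CohortParams, IsotopeContext, estimate_moto,
                     estimate_scope_envelope, gen_fish_cohort, invert_fixed_sw)
from otolife.thermometry import acid_fractionation_adjust

params = CohortParams.for_region("CA", n_fish=300, seed=4)
profiles, truth = gen_fish_cohort(params)
ctx = IsotopeContext.for_region("CA")

temps, moto = [], []
for fish in profiles:
    for iv in fish.milled_intervals:
        d18o = acid_fractionation_adjust(iv.d18o, iv.instrument)
        temps.append(float(invert_fixed_sw(d18o, params.seawater_d18o)))
        moto.append(float(estimate_moto(iv.d13c, ctx.dic_midpoint, ctx.diet_midpoint)))

env = estimate_scope_envelope(temps, moto)
print(env.optimal_temperature_c, truth.optimal_temperature_c)
```

Output:

```
1500 interval estimates from 300 fish
occupied 1 C bins: 9 (11.5-19.5 C)

 bin (C)   n    p5     p95
   11.5    22  0.111  0.363
   ...
   15.5   328  0.125  0.477
   ...
   19.5     8  0.173  0.412

estimated optimal temperature: 15.2 C
true optimal temperature:      15.4 C
```

Each fish contributes one reconstructed temperature and one metabolic
fraction per milled interval; the fitted 95th-percentile bound rises to
a maximum near 15.5 °C while the 5th-percentile bound climbs gently, so
the gap — the aerobic-scope analogue — peaks at 15.2 °C, within one bin
width of the generator's true optimum. The other scripts in
`examples/` walk through simulation, back-calculation with
uncertainties, both thermometry modes, and the survival index.

A command-line interface mirrors the library for file-based runs:

```sh
otolife simulate --region JP --n-fish 50 --seed 1 --out sim/
otolife run --config run.yaml        # backcalc → moto → temperature → scope → growthreg → lnrr
```

Table schemas are documented in `docs/formats.md`; the models and their
assumptions in `docs/methods.md`.

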