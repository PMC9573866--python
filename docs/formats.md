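# File formats

All interchange tables are UTF-8 CSV with a header row, '.' decimal
separator, and a leading comment line `# seed=<int> config_hash=<hex>`
recording the run that produced them. Read them with
`otolife.pipeline.read_table` (or `pandas.read_csv(..., comment="#")`).

## Input bundle

### otoliths.csv
One row per fish per daily increment.

| column | type | units | notes |
|---|---|---|---|
| fish_id | str | | unique per fish |
| region | str | | `JP` or `CA` |
| dph | int | days post hatch | strictly increasing per fish; starts at first_increment_dph + 1 |
| increment_um | float | µm | > 0 |

### fish.csv
One row per fish: catch metadata needed for back-calculation and
calendar month assignment.

| column | type | units |
|---|---|---|
| fish_id | str | |
| region | str | |
| first_increment_dph | int | days (JP 3, CA 8) |
| sl_catch_mm | float | mm |
| or_first_um | float | µm |
| or_catch_um | float | µm (≥ or_first_um + Σ widths) |
| hatch_date | str | ISO date |

### isotopes.csv
One row per fish per milled interval. Intervals are integer dph,
inclusive on both ends, ordered, non-overlapping.

| column | type | units |
|---|---|---|
| fish_id | str | |
| interval_start_dph | int | dph |
| interval_end_dph | int | dph |
| d13c_vpdb | float | ‰ VPDB |
| d18o_vpdb | float | ‰ VPDB, as measured (acid adjustment applied downstream) |
| instrument | str | `micro25C` or `auto72C` |

### hydro.csv
Surface (<30 dbar) hydrographic observations.

| column | type | units |
|---|---|---|
| year | int | |
| month | int | 1–12 |
| temp_c | float | °C, in [−2, 35] |
| salinity | float | practical scale, in [25, 38] |

### stock.csv
| column | type | notes |
|---|---|---|
| year | int | |
| ssb | float | spawning stock biomass, > 0 |
| recruits | float | > 0 |
| temp_anomaly | float | optional; standardized anomaly series |

### truth.csv (synthetic bundles only)
Per-interval ground truth: `fish_id, interval_start_dph,
interval_end_dph, m_true, t_mean_true_c, t_opt_true_c`.

## Outputs

- `backcalc.csv` — `fish_id, dph, or_um, sl_mm, sl_sd_mm`
- `moto.csv` — `fish_id, interval_start_dph, interval_end_dph,
  moto_mean, moto_sd, stage, outlier_flag`
- `temps.csv` — `fish_id, interval_start_dph, interval_end_dph,
  temp_c, method, month`
- `scope.json` — per stage: bins (center, n, p5, p95), upper/lower
  envelope coefficients, gap grid, `t_opt_c`, warning flag
- `growthreg.json` — per stage: n, Pearson r/p, BH-adjusted p,
  AIC table and chosen model with coefficients
- `lnrr.csv` — `year, ssb, recruits, lnrr`; fit statistics in the
  manifest / `lnrr_stats.json`
- `manifest.json` — region, seed, config hash, per-stage record
  counts, machine-readable warnings

## Exit codes (CLI)

0 success · 1 validation failure · 2 computation failure
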