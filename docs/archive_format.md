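# Ensemble archive format

All interchange files are classic NetCDF (NetCDF3), written and read
through xarray's `scipy` engine; any NetCDF tool can open them.

## `archive.nc` — the ensemble

| name          | dims                  | type  | notes                              |
|---------------|-----------------------|-------|------------------------------------|
| `min_O2`      | (run, column, time)   | f8    | units attr `mmol m-3` (required)   |
| `suboxic`     | (run, column, time)   | i1    | 1 where the raw solution clipped   |
| `node_phys`   | (run, param)          | f8    | physical (w, kappa, a) per run     |
| `node_std`    | (run, param)          | f8    | standardized coordinates           |
| `weight`      | (run,)                | f8    | quadrature weights, sum to 1       |
| `regime_code` | (column,)             | i4    | index into attr `regime_labels`    |
| `time`        | (time,)               | i4    | years, e.g. 1850, 2000, 2100       |

Global attributes: `param_names` (`"w kappa a"`), `regime_labels`
(comma-separated), `points_per_dim`, `seed`, `config_hash`.

Required to pass validation: dims `run`, `column`, `time`; variables
`min_O2` (with those dims, in that order), `node_phys`, `node_std`,
`weight`; weights summing to 1.

### Adapting external archives

`read_archive(path, var_map=..., unit_conversions=...)` renames the
file's dimensions/variables onto the schema (e.g.
`{"member": "run", "o2min": "min_O2"}`) and rescales `min_O2` whose
units attribute is not `mmol m-3` (built-in: `mol m-3` ×1000,
`umol l-1` ×1; extend via `unit_conversions`). Archives with
per-column `lat`/`lon` variables can use lat/lon-box region masks. An
external archive satisfying the schema flows through fit/sobol/maps
unchanged — the synthetic simulator is never required.

## `pce.nc` — chaos coefficients

`coeff_<field>` (term, column) per output field (the three time slices
and `delta_min_O2_1850_2100`); `alpha_w`, `alpha_kappa`, `alpha_a`
(term,) give each term's Hermite orders. Attr `field_names`.

## `sobol.nc` — variance fractions

`S_w`, `S_kappa`, `S_a`, `S_w_kappa`, `S_w_a`, `S_kappa_a`,
`S_w_kappa_a` (field, column) in percent, NaN where undefined, plus
`variance_total`. Attr `field_names` orders the `field` dimension.

## `maps.nc` — diagnostics

Per-column `mean_change`, `noise_to_signal`, `contemporary_spread`,
`contemporary_cv`, `low_variance_mask` (i1); attr
`rank_correlation_cv_vs_ns`.

## Text outputs

`regional_sobol.tsv` (region, n_columns, S_w … S_w_kappa_a,
variance_total) and `benchmark_regions.tsv` (parameter, rank, column,
regime, score_pct). `manifest.json` records config hash, seed, package
version and per-stage input/output SHA-256 checksums; it is the only
output containing timestamps.
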