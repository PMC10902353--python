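# livech4

Bottom-up, city-level livestock methane inventory toolkit.

`livech4` builds spatial-temporal dynamic emission factors (EFs) for
enteric fermentation and manure management, combines them with a
city-year-category activity panel under average-lifespan weighting, and
aggregates emissions city → province → nation. It ships a synthetic-data
generator that emulates a multi-city statistical-yearbook activity panel, a
gap-filling stage for cities with no breeding records, and Monte Carlo
uncertainty quantification.

## What it computes

- **Enteric fermentation (Tier 2)** — per-head EFs from a gross-energy
  intake model: net energy for maintenance, activity, lactation, pregnancy,
  growth and wool, partitioned through the REM/REG digestibility fractions;
  `EF = GE · (Ym/100) · 365 / 55.65` kg CH₄ head⁻¹ yr⁻¹. Dairy cattle use
  a milk-production regression (`30.8 · production^0.2 − 53.6`) instead.
  Minor species (horse, donkey, mule, poultry, rabbit, camel) use fixed
  Tier 1 lookup EFs.
- **Manure management** — per-head EFs from daily volatile-solids
  excretion, the manure's maximum methane capacity B₀, and
  management-system fractions weighted by climate-class-dependent methane
  conversion factors (MCFs). The climate class of each city-year follows
  its annual mean temperature (cool < 15 °C ≤ temperate < 25 °C ≤ warm).
- **Emission accounting** — both the year-end stock and the animals
  slaughtered within the year emit, each weighted by its average lifespan
  in months (`ALS/12`). Output unit is Gg CH₄ yr⁻¹.
- **Gap-filling** — missing city records are reconstructed from meat
  production via carcass weights, then converted to stock through a
  slaughter rate resolved city-first, then same-province, then
  province-mean. Body-weight series with missing years are extended with
  the mean geometric change rate.
- **Uncertainty** — Monte Carlo with uniform activity perturbations
  (half-width √3·CV) and truncated-normal EF perturbations, drawn per
  category and shared across cities; per-year empirical 95 % CIs.

All parameters (traits, manure systems, MCF table, lifespans, Tier 1 EFs,
CVs, subclass shares, carcass weights) live in a YAML registry
(`src/livech4/data/default_params.yaml`) and can be overridden with a user
config of the same layout.

## CLI

```bash
livech4 generate --out-dir synth --n-cities 347 --years 2010-2020 --seed 1
livech4 gapfill synth/activity_panel.csv synth/meat_production.csv --out filled.csv
livech4 ef enteric --regions P01,P02 --years 2010-2020 --traits synth/traits.csv
livech4 ef manure  --regions P01,P02 --years 2010-2020 --traits synth/traits.csv
livech4 compute filled.csv synth/climate.csv --traits synth/traits.csv --out-dir inventory_out
livech4 uncertainty filled.csv synth/climate.csv --traits synth/traits.csv --sims 10000 --seed 1
livech4 demo   # small end-to-end run
```

`compute` exports the six dataset files: city totals, city enteric, city
manure, city ruminant/nonruminant split, national+provincial pathway
structure, and per-category national series (`--format csv|xlsx`). A full
347-city × 2010–2020 panel yields 3817 / 3817 / 3817 / 7634 records in
files 1–4.

## Python API

```python
import livech4 as lc

spec = lc.SyntheticSpec(n_cities=347, years=(2010, 2020), seed=1)
result = lc.run_synthetic_pipeline(spec)       # generate → gap-fill → EFs → emissions
lc.export_dataset(result.cube, "inventory_out")

mc = lc.UncertaintySpec.from_params(result.params, n_sims=10_000, seed=1)
ci = lc.run_monte_carlo(result.panel, result.enteric_ef, result.manure_ef,
                        result.params, result.climate, mc)
```

## Layout

```
src/livech4/
  types.py       core enums and dataclasses
  params.py      parameter registry, climate classes, panel validation
  synthetic.py   synthetic panels, traits, climates, dataset variants
  gapfill.py     meat→slaughter→stock reconstruction, weight-series fill
  enteric.py     Tier 2 gross-energy EFs, dairy regression, Tier 1 lookup
  manure.py      volatile solids, MCF-weighted manure EFs
  inventory.py   emission assembly, aggregation, six-file export
  uncertainty.py Monte Carlo propagation and activity-data CV
  pipeline.py    end-to-end convenience wrapper
  cli.py         typer CLI
```
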