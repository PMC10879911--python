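# elevgrad

Analysis pipeline for insect occurrence surveys along elevational gradients:

- **Effort standardisation** — converts mixed sweep-net / hand-capture
  transect surveys into a single per-site effort index
  (`SE = surveys_net + total_obs_hand / mean_obs_net`).
- **Richness modelling** — per-site species richness (with a higher-taxon
  counting rule) modelled with a log-link quasipoisson GLM, reduced by
  backwards stepwise elimination driven by analysis-of-deviance F-tests.
- **Range–midpoint (Rapoport effect) test** — band-based elevational ranges
  and midpoints per species, polynomial regressions of range on midpoint up
  to order 4, compared by Gaussian AIC, adjusted R² and nested F-tests, with
  Stevens (band-wise) and Pagel (upper-extreme) comparators.
- **Synthetic data** — a configurable community/survey simulator with known
  ground truth (true range–midpoint relationship, occupied bands, effort and
  covariate gradients) for end-to-end parameter-recovery testing.

Sites live in 100-m elevation bands keyed by their lower bound (a site at
1650 m is in band 1600); a species seen in one band gets a 100-m range.

## CLI

```sh
# simulate a survey campaign (CSV tables + ground_truth.json)
elevgrad simulate --seed 42 --out-dir data/

# individual stages
elevgrad effort   --occurrences data/occurrences.csv --visits data/visits.csv --out effort.csv
elevgrad richness --sites data/sites.csv --occurrences data/occurrences.csv \
                  --effort effort.csv --out model.json
elevgrad rapoport --occurrences data/occurrences.csv --sites data/sites.csv \
                  --max-order 4 --method rohde --out rapoport.json

# full pipeline (synthetic scenario or your own CSVs) -> report bundle
elevgrad run --synthetic --seed 42 --out-dir out/
elevgrad run --occurrences occ.csv --sites sites.csv --visits visits.csv --out-dir out/
```

`elevgrad run` writes `effort.csv`, `richness_model.json`, `rapoport.json`,
`species_ranges.csv` and a human-readable `report.md`; every JSON artifact
carries version / config-hash / seed provenance.

### Input formats

Comma-delimited UTF-8 with header rows:

- `occurrences.csv`: site_id, visit_id, season, method (net|hand), taxon_id,
  rank (species|higher), parent_taxon, suborder, life_stage, count,
  distinct_flag
- `sites.csv`: site_id, study_area, elevation_band_lower, veg_cover,
  veg_max_height, veg_height75, veg_density, slope, aspect
- `visits.csv` (optional survey registry, makes zero-capture net surveys
  count towards effort): site_id, visit_id, season, method
- `vegetation_plots.csv` (optional pre-aggregation input): site_id,
  visit_season, max_height, height75, touch1..touch5, cover_vegetation,
  cover_rock, cover_bare

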