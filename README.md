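# betascape

Landscape-scale analysis of how habitat amount, fragmentation, spatial
distance, and regional climate drive tree beta diversity and endemism —
implemented as a reusable, fully synthetic-testable pipeline.

The package chains six stages:

1. **simulate** — generate a synthetic study: habitat rasters from a
   seeded-growth cluster process, species pools with five endemism
   categories, and inventory communities with distance-decay,
   fragmentation-homogenization, and endemism–cover structure.
2. **design** — filter inventories (effort ≥ 0.10 ha, DBH cutoff ≥ 5 cm,
   complete data), tessellate space into 100 km² pointy-top hexagons, and
   keep hexagons holding ≥ 2 inventories as landscapes.
3. **metrics** — per landscape: % habitat cover, number of patches, mean
   patch size (ha), mean nearest-neighbour distance between patches (m),
   mean pairwise distance among inventories (km), and climate means.
4. **beta** — abundance-based multi-site Bray–Curtis partition
   (total = balanced + gradient) and the rescaled Raup–Crick null-model
   index per landscape.
5. **endemism** — community-weighted mean endemism scores
   (exotic −1 … local endemic 3) and their per-landscape average.
6. **model** — Pearson screening (|r| ≤ 0.70), PCA, standardization,
   beta (logit link) and Gaussian regressions, dredge-style all-subsets AIC
   selection (ΔAIC ≤ 2 best set, marginality-constrained
   habitat_cover×n_patches interaction), VIF and Moran's I diagnostics.

## CLI

```sh
betascape all --config config.yaml --out runs/demo     # full chain
betascape report --out runs/demo                       # summary report
betascape simulate|design|metrics|beta|endemism|model --out runs/demo
```

A config file is YAML with `PipelineConfig` keys and a `simulation`
sub-mapping of `SimulationConfig` fields, e.g.:

```yaml
seed: 1
n_reps: 999
simulation:
  n_landscapes: 95
  cell_size: 500.0
  habitat_amount_range: [0.0, 1.0]
  inventories_per_landscape_range: [2, 12]
  pool_size: 140
  seed: 1
```

Every stage writes a delimited-text table plus a manifest (input hashes,
derived seed) into the run directory; reruns with the same config and seed
are byte-identical. Rasters are stored as ESRI ASCII grids
(`rasters/<landscape>__<year>.asc`). Exit codes: 0 ok, 2 configuration
error, 3 data error, 4 numerical failure.

### Table formats

- `inventories.csv`: inventory_id, landscape_id, x, y, year, effort_ha,
  dbh_cutoff_cm (coordinates in planar km; lon/lat supported in the metrics
  API via haversine distances).
- `abundances.csv`: wide matrix, rows = inventory_id, columns = species ids.
- `species.csv`: species_id, category, score.
- `landscapes.csv`: landscape_id, inventory_id, reference_year.
- `metrics.csv`, `beta.csv`, `endemism.csv`: one row per landscape.
- `selection_<response>.csv`: rank, AIC, ΔAIC, R², term, effect, p for all
  models in the ΔAIC ≤ 2 best set.

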