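# arealrisk

Areal disease-mapping toolkit for count data on administrative lattices:

- **Indirect standardization** — expected counts from the study-wide rate,
  standardized ratios (SR = observed/expected), crude admission rates.
- **Spatial autocorrelation** — global Moran's I (normality, randomization
  and permutation inference), Getis-Ord General G, and local Gi* hot/cold
  spot classification, all with analytic moments validated against
  exhaustive permutation.
- **Spatial scan statistics** — purely spatial Poisson scan over circular
  (centroid-distance) windows: likelihood-ratio scoring, conditional
  Monte Carlo inference, primary and non-overlapping secondary clusters.
- **Hierarchical Bayesian smoothing** — six Poisson log-linear model
  structures (intercept / covariate / iid heterogeneity / CAR clustering),
  a Gaussian-ICAR and a robust L1 CAR variant, adaptive
  Metropolis-within-Gibbs sampling, Gelman-Rubin diagnostics, posterior
  summaries and DIC model comparison.
- **Synthetic data** — grid lattices with log-linear risk surfaces, ICAR
  clustering sampled via the graph-Laplacian pseudo-inverse, and embedded
  high-risk circular clusters, with a full truth record for recovery tests.
- **Pipeline CLI** — one command running standardize → autocorrelation →
  scan → model sweep → DIC table → smoothed-SR table, deterministically
  seeded, with CSV/JSON reports.

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with the end-to-end acceptance criteria
(sampler conjugate oracle, parameter-recovery coverage, cluster
recovery, null-calibration of scan p-values) at reduced replication.

## CLI

```bash
# generate a 57-area synthetic dataset (CSV + GAL + GeoJSON + truth JSON)
arealrisk simulate --preset shenzhen-like --seed 1 --out data/

# spatial autocorrelation on the SR surface
arealrisk autocorr --area-csv data/areas.csv --geojson data/areas.geojson \
    --stat moran --permutations 999 --seed 1

# Poisson scan for high-rate clusters
arealrisk scan --area-csv data/areas.csv --geojson data/areas.geojson \
    --mc 999 --seed 1

# fit one Bayesian smoothing model (1..6)
arealrisk fit --area-csv data/areas.csv --geojson data/areas.geojson \
    --model 5 --car l1 --chains 3 --iter 20000 --burnin 2000 --seed 1

# full pipeline from a YAML config
arealrisk run --config config.yaml
```

A minimal `config.yaml`:

```yaml
area_csv: data/areas.csv
geojson: data/areas.geojson
out_dir: out/
seed: 1
scan_mc: 999
models: [1, 2, 3, 4, 5, 6]
mcmc:
  n_chains: 3
  n_iter: 20000
  burn_in: 2000
```

## Layout

- `src/arealrisk/areal_core.py` — lattice/weights data model, queen/rook
  contiguity from polygons, GAL/GeoJSON/CSV I/O.
- `src/arealrisk/standardization.py` — expected counts, SR, rates.
- `src/arealrisk/autocorrelation.py` — Moran's I, General G, Gi*.
- `src/arealrisk/scan.py` — Poisson scan statistic.
- `src/arealrisk/hbayes.py` — Bayesian models, MCMC, DIC, diagnostics.
- `src/arealrisk/synthetic_data.py` — scenario generator and presets.
- `src/arealrisk/pipeline.py`, `src/arealrisk/cli.py` — orchestration.
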