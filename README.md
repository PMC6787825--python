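# camtrapniche

Occupancy, co-occurrence and diel-activity analysis for camera-trap surveys
of small-carnivore communities. The package covers the full niche-analysis
workflow:

- **`detections`** — record tables, the 1-hour independence filter,
  detection histories collapsed into fixed-length occasions, and survey
  summaries (independent events, capture rate per 100 trap nights, naive
  occupancy).
- **`habitat`** — station vegetation covariates from plot tallies (stem
  densities, canopy structure, trail widths, undergrowth), Shannon / Pielou /
  Fisher's-alpha diversity indices, and |r| > 0.70 collinearity screening.
- **`occupancy`** — single-season, single-species occupancy likelihood with
  logit links and covariates; ML fitting; AICc/QAICc; parametric-bootstrap
  goodness of fit with c-hat; Akaike-weight model averaging; and the
  detection-first, three-stage selection workflow.
- **`cooccurrence`** — conditional two-species occupancy (dominant /
  subordinate parameterisation psiA, psiBA, psiBa, pA, pB, rA, rBA, rBa),
  constrained submodels ranked by AIC, and species interaction factors for
  occupancy (Phi) and detection (delta) with delta-method intervals.
- **`activity`** — von Mises kernel densities of diel activity, Taylor-type
  plug-in bandwidth, 50%/95% highest-density isopleths, overlap
  coefficients (plain and isopleth-conditional), and with/without-dominant
  comparisons.
- **`simulate`** — a fully seeded survey simulator (stations, effort,
  covariates, records, two-species interaction scenarios, diel mixtures)
  used by the tests and calibration runs.
- **`pipeline` / `cli`** — end-to-end orchestration with CSV/JSON reports.

## CLI

```bash
camtrapniche simulate --out sim/ --seed 7
camtrapniche summarize --records sim/records.csv --effort sim/effort.csv
camtrapniche occu --history H.csv --covariates C.csv \
    --p-candidates trail_width_max,season --psi-candidates shannon_h
camtrapniche occu2 --history-a dominant.csv --history-b subordinate.csv
camtrapniche activity --records sim/records.csv --pairs "civet:marsh_mongoose"
camtrapniche run --config pipeline.yaml --out report/
```

A pipeline config is plain YAML with `PipelineConfig` fields, e.g.

```yaml
scenario_seed: 8      # simulate inputs; or give records/effort/covariates paths
seed: 8
min_events: 50
n_boot: 0
```

## File formats

- records CSV: `station,species,timestamp` (ISO 8601, local clock time);
- effort CSV: `station,deploy,retrieve[,gap_start,gap_end]*`;
- history CSV: `station,occ_1..occ_K` with `NA` for fully inactive occasions;
- covariate CSV: wide table keyed by `station`.
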