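# mtseason

Seasonal (cosinor) analysis of mitochondrial DNA abundance:

- **`mtseason.abundance`** — mtDNA abundance from coverage summaries:
  mitochondrial mean coverage ÷ total mapped reads, single-pass 4×IQR
  outlier exclusion, standardization of the surviving ratios.
- **`mtseason.cosinor`** — single-harmonic sine–cosine regression of a
  standardized outcome on month of measurement; amplitude
  `√(β_cos² + β_sin²)`, four-quadrant acrophase `atan2(β_sin, β_cos)` and
  displacement, each with delta-method standard errors, Wald summaries, a
  2-df joint seasonality test and calendar (peak/trough month) conversion.
- **`mtseason.scan`** — marker×season interaction models
  (`y = β0 + β1·M + β2·cosw + β3·sinw + β4·M·cosw + β5·M·sinw + covariates`),
  per-marker changes in amplitude (% of a reference amplitude), acrophase
  (months / percent of a month) and displacement; batch scans with
  Bonferroni (3 tests per marker) or fixed-threshold policies,
  incident-disease coding, composite phenotypes, mortality interaction,
  z-score correlations and the genomic inflation factor λ_GC.
- **`mtseason.covariates`** — lifestyle covariate coding with
  missing-to-reference rules, pack-years group-median imputation, the 2009
  CKD-EPI eGFR, a self-reported-ailment frailty index, and
  log2 + scale omics preprocessing (mean or iterative low-rank imputation).
- **`mtseason.simulate`** — synthetic cohorts with known seasonal ground
  truth (recruitment months, covariates with configurable moments, markers
  modulating displacement/amplitude/acrophase, incident diseases, death with
  follow-up) plus coverage summaries consistent with a latent abundance.
- **`mtseason.io` / `mtseason.cli`** — tab-delimited tables with metadata
  headers, mosdepth-summary parsing (`MT`/`chrM`), reads manifests,
  deterministic scan output, YAML/JSON configuration.

## CLI

```sh
# 1. simulate a cohort with known ground truth
mtseason simulate --config examples/config.yaml --out out/

# 2. coverage summaries -> filtered, standardized abundance
mtseason quantify --coverage-dir out/coverage \
    --manifest out/reads_manifest.tsv --out out/abundance.tsv

# 3. overall seasonal model
mtseason fit-season --cohort out/cohort.tsv --adjust age --out out/season.json

# 4. marker x season interaction scan (Bonferroni over 3 tests/marker)
mtseason scan --cohort out/cohort.tsv --markers m1,m2 --adjust age \
    --seed 5 --out out/scan.tsv

# 5. diagnostics: lambda_GC per stream, z-score correlations
mtseason report --scan out/scan.tsv
```

A minimal simulation config:

```yaml
simulate:
  n_individuals: 5000
  seed: 7
  amplitude_true: 0.092      # outcome SD units
  acrophase_true: -0.14      # radians, peak just before New Year
  noise_sd: 1.0
  covariates:
    - {name: age, dist: normal, mean: 56.92, sd: 8.0, effect: -0.005}
  markers:
    - {name: ever_smoked, dist: binary, prevalence: 0.456,
       displacement: -0.1, amplitude_change: -0.02}
  diseases:
    - {name: cardiovascular, incidence: 0.1, amplitude_ratio: 0.835}
  death: {rate: 0.05, amplitude_ratio: 0.772, followup_range: [0.01, 15.5]}
```

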