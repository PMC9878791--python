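# phenodisc

Discrimination analysis of mixed-type phenotyping tables.

Given a table of individuals (rows) by recorded variables (columns) — mixed
quantitative and qualitative, optionally organized in test groups via a `::`
header separator (`HotPlate50::Latency`) — phenodisc identifies the
variables that best discriminate a categorical dependent variable
(genotype, sex, treatment). The pipeline:

1. **Preprocessing** — identifier anonymization, removal of low-information
   variables (quantitative with <3 unique values, qualitative with <2
   levels), missing-value imputation (stratum mean for a single missing
   cell; bootstrapped predictive-mean-matching regression otherwise), and
   standardization.
2. **Feature pre-selection** — removal of highly correlated predictors
   (default `|r| > 0.75`, greedy mean-correlation rule, with per-pair
   p-values and Cramér's V for qualitative pairs), and a second optional
   selection keeping variables whose association with the first three
   factor dimensions exceeds 30% (the *sel30* model).
3. **Factor analysis** — from-scratch mixed-data PCA (generalized SVD over
   the standardized quantitative block and the frequency-weighted indicator
   matrix) and multiple factor analysis with group weighting
   (`1/λ₁(group)`), with eigenvalues, individual coordinates, squared
   loadings (correlation² / η²), level coordinates, group contributions,
   partial axes, partial individual coordinates and cosine similarities.
4. **Classification** — four importance-ranking classifiers (binary
   logistic GLM, multinomial log-linear model, elastic net tuned over
   (alpha, lambda), random forest) fit on each of the three predictor sets
   (*full*, *decorrelated*, *sel30*), with per-class variable importances
   scaled so the top variable scores 100, and bootstrap-resampled accuracy.
5. **Visualization** — nine publication plots with machine-readable TSV
   twins, written to conventionally named folders (`partialAxes_Plot1`,
   `groupContribution_Plot2`, `individualCoordinates_Plot3` incl. a 3D HTML
   view, `sqload_Plot4`, `quantitativeVarCoordinates_Plot5`,
   `levelsComponents_Plot6`, `paralelPlot`, `importance_variables`,
   `cumulativeVariance`).

A seeded synthetic-cohort generator (`phenodisc.synthetic`) produces
realistic genotype × sex cohorts with planted linear-dosage, non-linear and
noise variables for end-to-end testing without any external data.

## CLI

```bash
# simulate a cohort
phenodisc simulate --out cohort.tsv --truth truth.json --seed 7

# run the three-model analysis on a CSV/TSV/XLSX table
phenodisc run --input cohort.tsv --dependent Genotype --conditioning Sex \
    --outdir results/ --seed 7
```

Exit codes: 0 success, 2 configuration error, 3 data error, 4 stage failure.
Outputs include a `run_manifest.json` with SHA-256 checksums of every table
written; reruns with the same seed are bit-identical.

## Library

```python
from phenodisc import (RunConfig, run_pipeline, SyntheticSpec, generate_cohort)

table, truth = generate_cohort(SyntheticSpec(seed=1, missing_rate=0.05))
config = RunConfig(dependent="Genotype", conditioning=("Sex",), seed=1)
manifest = run_pipeline(table, config, "out/")
print(manifest.model_sets["sel30"])
```

## Tests

```bash
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria: algebraic
invariants of the factor core (eigen-oracle equivalence against direct
eigendecomposition and correspondence-analysis oracles, inertia
conservation, MFA weight normalization), planted-signal parameter recovery
over 50 seeded cohorts, and null accuracy calibration.

Two integration tests reproduce published cohort numbers and require the
original supplementary Excel tables, which cannot be downloaded in an
offline environment. To enable them, place the files under `data/` as
`scn10a_table_s2.xlsx` and `scn9a_table_s4.xlsx`, each with a sibling
`<name>_config.json` holding a `RunConfig` JSON that declares the id,
dependent and conditioning columns. Without these files the tests skip.

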