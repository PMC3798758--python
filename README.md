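# progmet

Prognostic metagene discovery and proliferation-conditional survival analysis
for expression cohorts.

Given a log2 expression matrix (probes × samples), a clinical table with
distant-metastasis-free survival (DMFS), and a probe→gene map, `progmet`
runs a supervised signature-discovery pipeline:

1. **Follow-up delimiting** — administrative censoring at a 10-year window.
2. **Balanced randomization** — iterative half-splits monitored by
   standardized differences (< 10%) and a DMFS log-rank equivalence
   criterion (p > 0.99), yielding paired training/test cohorts.
3. **Gene screening** — per-probe univariable Cox (Breslow partial
   likelihood, likelihood-ratio test) with Benjamini–Hochberg q-values;
   probes pass at p < 0.01 **and** q < 0.10.
4. **Clustering & metagenes** — average-linkage hierarchical clustering on
   correlation distance; maximal dendrogram branches with average pairwise
   Pearson r ≥ 0.6 become subclusters; each subcluster is scored as a
   metagene (probes collapse to genes first, then genes are averaged).
5. **Tertile stratification** — training-derived tertile cut-points
   (low/intermediate/high coded 1/2/3) applied to the held-out half.
6. **Subtype assignment** — Spearman nearest-centroid (SSP-style, 0.1
   correlation floor) plus Euclidean Claudin-Low calls.
7. **Conditional analyses** — per proliferation-tertile (and per subtype /
   treatment) Kaplan–Meier, log-rank and ordinal Cox models of the immune
   metagene tertiles; multivariable models with conventional covariates;
   combinatorial low/high immune-tertile profiles.

A first-class synthetic-data module generates multi-study cohorts with
planted proliferation and correlated immune latent factors, probe-level
redundancy, batch offsets, clinical covariates, and survival times whose
immune effects are active only in the top proliferation tertile — with
ground-truth labels for parameter-recovery testing.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests (hypothesis) for
the stated invariants, and `tests/test_acceptance.py` with one test per
acceptance criterion (statistical engine oracles, FDR control, randomization
balance, subcluster thresholds, parameter recovery, determinism).

## CLI

```sh
progmet simulate --seed 3 --out run/cohort
progmet randomize --clinical run/cohort/clinical.tsv --seed 3 --out run/split.json
progmet select-genes --expr run/cohort/expression.tsv --clinical run/cohort/clinical.tsv --out run/genes.tsv
progmet cluster --expr run/cohort/expression.tsv --out run/clusters
progmet metagene --expr run/cohort/expression.tsv --probe-map run/cohort/probe_map.tsv \
    --subclusters run/clusters/subclusters.json --out run/metagenes
progmet analyze --tertiles run/metagenes/tertiles.tsv --clinical run/cohort/clinical.tsv --out run/analysis.tsv
progmet run-all --seed 3 --out run/full       # full two-way pipeline, synthetic cohort
```

`run-all` accepts a YAML `PipelineConfig` (`--config`) for file-based inputs
(expression/clinical/probe-map/centroid TSVs) and all thresholds; every run
writes a `manifest.json` recording versions, seeds, thresholds and per-stage
counts, and reruns with the same config are byte-identical.

## Library

```python
from progmet import (SimConfig, simulate_cohort, delimit_followup, balanced_split,
                     screen_genes, select_prognostic, hcluster, extract_subclusters,
                     build_metagene, tertile_cutpoints, assign_tertiles,
                     conditional_analysis, multivariable_models)

expr, clinical, truth = simulate_cohort(SimConfig(seed=1))
clinical = delimit_followup(clinical, horizon_years=10)
table = screen_genes(expr, clinical)
probes = select_prognostic(table, p_thresh=0.01, q_thresh=0.10)
```

File formats are plain TSV (expression: probes × samples with a header of
sample ids; clinical: one row per sample with documented column names;
probe map: two columns; centroids: genes × subtypes) and JSON for structured
results; dendrograms export to Newick.

## Notes

- Cox models use the Breslow tie convention, Wald 95% CIs, and two-sided
  tests throughout; ties at tertile cut-points go to the lower tertile;
  quantiles are linear-interpolation ("type 7"). These conventions are
  recorded in output metadata because cut-points are serialized and applied
  across cohorts.
- Missing expression values are rejected at load; imputation is out of
  scope. Unknown clinical categories are kept as a distinct level and
  excluded listwise per analysis.
- Normalization and cross-study batch correction are upstream concerns; a
  per-study centering hook exists as plumbing only.
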