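# tnbc-immune

Immuno-cluster discovery and systemic-inflammation association analysis for
triple-negative breast cancer (TNBC) expression cohorts.

TNBC is an aggressive breast cancer subtype whose outcome and therapy
response depend strongly on the tumor immune microenvironment.  This package
implements, as a tested and reusable pipeline, the analysis strategy of
decomposing a bulk expression cohort into immuno-clusters and asking whether
cheap, routinely collected blood-count markers of systemic inflammation
mirror the local immune state:

1. **Immuno-clustering** — consensus non-negative matrix factorization (NMF,
   squared-Euclidean multiplicative updates) of the immune-gene submatrix
   with gene-subsampled runs, rank selection by the cophenetic correlation
   coefficient, and a two-step refinement (exclude under-sized clusters,
   merge the most Pearson-correlated centroids) down to three clusters
   ImA/ImB/ImC ordered by immune activity ("hot" / intermediate / "cold").
2. **Immune signature scoring** — per-sample cytolytic activity
   `CYT = log2-geometric-mean(GZMA, PRF1)`, the 18-gene tumor inflammation
   signature (TIS), the three-gene aggressive score
   `-0.393·CCL5 + 0.443·DDIT4 + 0.490·POLR1C`, the integrative score
   `IMS = CYT·TIS − aggressive`, single-sample GSEA (rank-weighted
   running-sum enrichment), ESTIMATE-style stromal/immune scores with the
   purity transform `cos(0.6049872018 + 0.0001467884·score)`, and a 0–10
   immunophenoscore.
3. **Deconvolution** — immune-cell fractions per sample by linear ν-support
   vector regression against a user-supplied reference signature matrix,
   with a permutation-null confidence measure.
4. **Inflammation association** — platelet-to-lymphocyte (PLR) and
   neutrophil-to-lymphocyte (NLR) ratios from complete blood counts, related
   to clusters and scores by Kruskal–Wallis tests, Spearman correlation,
   2×2 odds ratios with Wald 95% CIs, binomial and multinomial logistic
   regression (crude and age-adjusted), exact k×2 Fisher tests,
   Kaplan–Meier 5-year disease-free survival with log-rank tests, and
   quadrant classification of score versus time-to-event.
5. **Synthetic cohorts** — a first-class generator producing 54-sample
   cohorts with three latent immune clusters (sizes 15/18/21), graded
   immune-gene activation, TILs driven by CD8 enrichment, per-cluster PLR
   medians 132/162/176 and cluster-dependent recurrence hazards, so every
   stage can be validated against ground truth.

It is aimed at computational biologists who want either the end-to-end
pipeline (CLI) or the individual building blocks (library functions over
pandas DataFrames).

## Worked example

Run the full pipeline on a simulated default cohort:

```sh
tnbc-immune run --config run.yaml
```

with `run.yaml`:

```yaml
seed: 11
out_dir: demo_out
simulate: {}
```

or equivalently from Python:

```python
from tnbc_immune import RunConfig, run_pipeline, report_summary
result = run_pipeline(RunConfig(seed=11, out_dir="demo_out", simulate={}))
print(report_summary(result))
```

which prints (abridged):

```
| cluster |  n | median_cyt | median_tis | median_aggressive | median_ims | median_plr | pct_tils_high | n_events |
|:--------|---:|-----------:|-----------:|------------------:|-----------:|-----------:|--------------:|---------:|
| ImA     | 15 |       8.00 |       7.57 |              3.09 |      56.49 |     131.46 |         86.67 |        2 |
| ImB     | 21 |       7.07 |       6.74 |              3.59 |      44.07 |     179.35 |         42.86 |        7 |
| ImC     | 18 |       6.45 |       6.11 |              4.55 |      34.40 |     176.78 |         11.11 |        9 |

| marker | contrast                | estimate |      p | ci_low | ci_high |
|:-------|:------------------------|---------:|-------:|-------:|--------:|
| plr    | kruskal_wallis_clusters |  18.8215 | 0.0001 |        |         |
| plr    | multinomial_ImB vs ImA  |   1.6357 | 0.0008 | 1.2276 |  2.1793 |
| plr    | multinomial_ImC vs ImA  |   1.5899 | 0.0015 | 1.1947 |  2.1157 |
| plr    | spearman_vs_tis         |  -0.4629 | 0.0004 |        |         |
| plr    | or_high_aggressive      |   4.0000 | 0.0163 | 1.2901 | 12.4023 |
```

Reading the output: the consensus NMF selected rank 3 and recovered the
generating clusters exactly (adjusted Rand index 1.0 against the simulation
truth).  The inflamed cluster ImA has the highest cytolytic activity and
inflammation scores, the lowest aggressive score, the most TILs-high tumors
and the fewest recurrence events — and the *lowest* median PLR, while the
multinomial odds ratios (per 10 PLR units, age-adjusted) and the negative
TIS–PLR Spearman correlation quantify the same inverse link between
systemic inflammation and local tumor immunity that motivates the pipeline.

Each stage is also available standalone (`tnbc-immune simulate | score |
cluster | deconvolve | associate | report`), reading and writing plain
TSV/CSV/GMT files; every run writes a JSON manifest with seeds, config hash
and per-stage timings, and identical config + seed reproduces byte-identical
outputs.

Real cohorts enter the same way: a genes × samples TSV or GCT 1.2
expression matrix (log2, gene-level symbols), a CBC CSV (neutrophils,
lymphocytes, platelets in 10⁹ cells/L) and a clinical CSV (age, TILs %, DFS
time and event flag).  Gene panels (TIS, CD8, ESTIMATE, immunophenoscore
weights) ship as editable text under `src/tnbc_immune/data/` and can be
replaced by any GMT/CSV of the same shape.

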