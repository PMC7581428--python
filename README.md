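# cagdyn

Analysis pipeline for a Huntington-disease mouse cross design: somatic CAG
expansion-index quantification from fragment-analysis peak traces,
negative-binomial differential expression across the four Htt × Hdac2
genotype groups, directional DEG-overlap and rescue/exacerbation
classification, a gene-set permutation test for reduced relative impact of
the disease allele, nuclear-pathology intensity correlation, and the
survival-adjusted contraction-assay fold change — together with synthetic
data generators so every stage runs and is testable at desk scale, with no
external downloads.

## Modules

| module | what it does |
| --- | --- |
| `cagdyn.stats_core` | shared primitives: unpaired t-test (pooled/Welch) with 95% CI, Pearson correlation, Benjamini-Hochberg step-up, one-sided Fisher exact test |
| `cagdyn.instability` | peak-table parsing, modal-allele calling, expansion index, cohort comparison, contraction-assay fold change |
| `cagdyn.expression` | detection/length/biotype gene filters, log-CPM, sample PCA, per-gene NB likelihood-ratio test for the five genotype contrasts (plus a log-CPM linear-model cross-check) |
| `cagdyn.rescue` | directional overlap of two DEG tables, Fisher overlap tests, rescue classification via the endpoint t-test criterion, relative-impact permutation test, cross-study concordance, GMT gene-set enrichment |
| `cagdyn.pathology` | per-image intensity-per-nucleus summaries, per-mouse phenotypes, intensity-vs-expansion correlation |
| `cagdyn.synthetic` | trace-cohort, planted-class count-matrix, and intensity simulators with ground-truth labels |
| `cagdyn.pipeline` / `cagdyn.cli` | YAML-config orchestration with a run manifest, and the `cagdyn` CLI |

## CLI

All stages are subcommands of a single `cagdyn` entry point
(exit codes: 0 success, 2 invalid input, 3 runtime failure):

```bash
# expansion indices from a long-format peak TSV (sample_id, repeat_units, height)
cagdyn expansion-index --peaks peaks.tsv --min-rel-height 0 --out out/

# survival-adjusted contraction-assay fold changes over a vehicle control
cagdyn contraction --records records.tsv --reference DMSO --out folds.tsv

# differential expression for one of the five genotype contrasts
cagdyn de --counts counts.tsv --meta meta.tsv --contrast 3 --method nb-lrt \
          --covariates sex --out out/

# directional overlap of two DEG tables, then rescue classification
cagdyn overlap --deg-a deg3.tsv --deg-b deg2.tsv --alpha 0.05 --out ov/
cagdyn rescue --expr logcpm.tsv --meta meta.tsv --overlap ov/overlap_genes.tsv --out rescue/

# relative-impact permutation test
cagdyn permtest --lfc-wt deg_wt.tsv --lfc-ko deg_ko.tsv --set genes.txt \
                --n-perm 100000 --seed 7 --out perm.json

# gene-set enrichment against a GMT collection
cagdyn enrich --query q.txt --background bg.txt --gmt sets.gmt --out enrich.tsv

# pathology correlation
cagdyn correlate --pheno image_quant.tsv --expansion expansion_index.tsv

# simulators (emit the same TSV formats the analysis stages read)
cagdyn simulate-traces --config traces.yaml --out sim/
cagdyn simulate-counts --config counts.yaml --out sim/
cagdyn simulate-pathology --expansion sim/expansion_index.tsv --out intensity.tsv

# multi-stage run from a single config
cagdyn run --config run.yaml
```

Example `run.yaml`:

```yaml
out_dir: run1
seed: 11
stages:
  - stage: simulate_traces
    n_mice_per_group: 10
    n_cells: 5000
    genotype_rate: {WT: 3.0, KO: 2.5}
  - stage: expansion_index
  - stage: compare_groups
```

Each run writes a `manifest.json` (config hash, seed, stage outputs,
package version); identical config + seed yields byte-identical outputs.

## Notes on the expansion index

For a trace with modal (highest) peak height `H0` and expansion peaks
strictly to the right with heights `h_i` at repeat distances `d_i`, the
index is `sum_i d_i * h_i / (H0 + sum_j h_j)`. Contraction peaks (left of
the modal allele) enter neither numerator nor denominator; by default no
relative-height filter is applied. The index equals the mean positive
repeat-length change of the underlying cell population.
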