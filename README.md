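# mirdeq

A tested, reusable pipeline for two-group miRNA deep-sequencing read-count
analysis:

* **counts_io** — TSV count matrices, sample tables, miRBase-dialect GFF3
  annotations (1-based on disk, 0-based half-open internally), DE result
  tables with `N/A` for undefined fold changes.
* **normalization** — mean-expression filtering (`mean < 5` removed),
  quantile-quantile scaling of every sample onto the per-miRNA mean
  reference (tie-averaged rank matching; a global per-sample linear scale is
  available as an alternative), and log10 transformation with a pseudocount.
* **diffexp** — pooled-variance two-tailed t tests on the log10 values
  (Welch behind a flag), Holm step-down adjustment with configurable family
  size, direction-oriented fold changes, signature selection
  (`p_adj < alpha`) and the clustering-set rule (`fold > 2` and mean
  difference `> 100` normalized reads).
* **multivariate** — mean-centered PCA with deterministic sign convention,
  UPGMA (average-linkage) sample clustering on Pearson or Euclidean
  distance, and a two-cluster purity check against group labels.
* **genomic_clusters** — polycistronic cluster detection by single-linkage
  chaining of precursor intervals (arms collapse to one interval; default
  gap 10 kb) and per-cluster deregulation summaries on raw p-values.
* **rtpcr** — comparative-CT (2^-ddCT) relative quantification with an
  endogenous control assay and a calibrator sample; replicate-wise or
  propagated SD.
* **seed_targets** — strict Watson-Crick seed-site scanning of 3'-UTRs
  (6mer / 7mer-A1 / 7mer-m8 / 8mer) and deterministic site-disrupting
  mutagenesis.
* **synthetic_data** — negative-binomial count matrices with planted fold
  changes and heterogeneous depths, GFF3 with planted clusters, CT tables
  with planted folds, and UTRs with planted sites; all bit-reproducible
  given (config, seed).
* **pipeline / cli** — end-to-end orchestration with a YAML config, stage
  logging to stderr, and a JSON run report.

## Command line

```sh
# generate synthetic inputs with planted ground truth
mirdeq simulate counts --seed 17 --out data/
mirdeq simulate gff    --seed 17 --out data/

# stage by stage
mirdeq normalize --counts data/counts.tsv --min-mean 5 --method quantile \
    --out data/normalized.tsv
mirdeq diffexp --normalized data/normalized.tsv --samples data/samples.tsv \
    --alpha 0.05 --family-size auto --out data/de.tsv
mirdeq cluster-samples --normalized data/normalized.tsv --out data/dendro.json
mirdeq clusters --gff data/mirnas.gff3 --de data/de.tsv --max-gap 10000 \
    --out data/clusters.tsv
mirdeq rtpcr --ct data/ct.csv --control U6 --calibrator CT-N01 --out folds.csv
mirdeq scan --utr data/utrs.fasta --mirna-seq ACTCTTTCCCTGTTGCACTAC \
    --out sites.tsv

# or everything at once
mirdeq run --config run.yaml
```

A minimal `run.yaml`:

```yaml
counts: data/counts.tsv
samples: data/samples.tsv
gff: data/mirnas.gff3     # optional
out_dir: results/run
alpha: 0.05
family_size: auto
```

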