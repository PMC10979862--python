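# hypertx

Quantify RNAPII hypertranscription from paired tumor/normal mapped-fragment
data. The package implements a complete downstream analysis for
CUT&Tag/CUTAC-style fragment files:

- **fragments** — BED3 I/O with validation, exact-coordinate duplicate
  removal, replicate pooling, fragment-count equalization by downsampling,
  QC filtering (>= 100,000 fragments and >= 10,000,000 bp of total fragment
  length), and mitochondrial signal accounting.
- **coverage** — genome-scaled normalized per-bp tracks (uniform coverage
  equals 1.0 at every position; tracks always sum to the genome size),
  per-region averaged/summed signal, bedGraph I/O, and region subtraction
  with `intersect -v` semantics.
- **hyper_stats** — per-element Tumor − Normal differences (Bland-Altman and
  MA coordinates), rankings and rank-ordered difference curves, cross-pair
  max-difference composites, histone-cluster excess with a paired t-test,
  and chrM comparison.
- **peaks** — paired-control sparse-enrichment peak calling: maximal positive
  signal blocks scored by AUC, with a threshold maximizing the
  target-vs-control block-fraction gain ("relaxed" takes the smallest
  threshold within 90% of the maximum gain).
- **amplicon** — 1-kb tiling of tumor/normal signal, local polynomial
  (LOESS) smoothing with tricube weights, broad-summit detection with
  promoter anchoring, and windowed fold change.
- **cluster** — region × sample raw count matrix, TF-IDF normalization,
  top-feature selection, scaling, PCA and a seeded 2-D UMAP embedding.
- **synthetic** — a generative model for paired tumor/normal fragment sets
  with planted hypertranscribed elements, histone-cluster upregulation,
  chrM depletion, duplicates, and amplified segments carrying Gaussian
  summits; every run returns a truth ledger used by the test suite.
- **pipeline / CLI** — a `hypertx` command orchestrating all stages with a
  YAML config, deterministic seeds and a checksummed run manifest.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the top-level acceptance criteria
(normalization identity, brute-force oracle equivalence, peak-caller
asymmetry and planted-block recovery, hypertranscription/histone/chrM
recovery, amplicon and summit recovery, clustering purity, and the LOESS
contract), all exercised on synthetic data with planted ground truth.

## CLI

```sh
hypertx demo --seed 1 --out demo_run      # simulate + full pipeline
hypertx simulate --seed 2 --out sim       # synthetic pair + truth ledger
hypertx qc sim/tumor.bed --genome sim/genome.chrom.sizes
hypertx dedup sim/tumor.bed --genome sim/genome.chrom.sizes --out dedup.bed
hypertx equalize t.bed n.bed --genome g.sizes --seed 1 --out-a t_eq.bed --out-b n_eq.bed
hypertx tracks t_eq.bed --genome g.sizes --out t.bedgraph
hypertx signal t.bedgraph --genome g.sizes --regions regions.bed --out signal.tsv
hypertx hyper t.bedgraph n.bedgraph --genome g.sizes --regions regions.bed --out diff.tsv
hypertx histone t1.bed n1.bed t2.bed n2.bed --genome g.sizes --histones hist.bed
hypertx mito t.bed n.bed --genome g.sizes
hypertx peaks t.bedgraph n.bedgraph --genome g.sizes --mode relaxed --out peaks.bed
hypertx amplicon t.bedgraph n.bedgraph --genome g.sizes \
    --window chr1:500000-1500000 --bin 1000 --span 0.2 --out-prefix amp
hypertx cluster s1.bed s2.bed s3.bed --genome g.sizes --regions regions.bed \
    --pcs 50 --seed 7 --out embedding.tsv
hypertx run --config pipeline.yaml       # full pipeline from a YAML config
```

## File formats

Fragments are BED3 (tab-separated, 0-based half-open); genomes are
two-column chrom-sizes text; coverage tracks are 4-column bedGraph; region
sets are BED with id and class columns; count matrices are MatrixMarket with
row/column id sidecars; configs are YAML; truth ledgers and manifests are
JSON. All deliverable formats are plain text.
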