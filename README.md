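# splicescape

Analysis toolkit for alternative-splicing heterogeneity in tumor cohorts.
It covers the full path from junction counts to biology:

- **PSI estimation** (`splicescape.psi`) — per-event, per-sample percent
  spliced in under a two-isoform model with effective-length normalization.
  Point estimate is the plug-in MLE `I*lS / (I*lS + S*lI)`; a uniform prior
  on the read-space fraction gives a closed-form Beta posterior and exact
  equal-tailed 95% credible intervals via a monotone transform.
- **Event filtering** (`splicescape.filtering`) — sample QC (drop samples
  with >40% undetected events) and the three event criteria: PSI range >0.6,
  SD >0.1 (ddof=1), and CI width <0.5 in >80% of detected samples; plus
  intersection of kept sets across cohorts.
- **Subtype discovery** (`splicescape.clustering`) — consensus k-means over
  resampled sample subsets in Pearson-correlation geometry with row-wise
  normalization; final labels from average-linkage clustering of the
  consensus matrix; silhouette-ranked representative selection.
- **Signature & AS score** (`splicescape.signature`) — random-forest Mean
  Decrease Gini ranking of events against cluster labels, survival-direction
  grouping (group 1 = higher PSI in the worse-survival cluster), and the AS
  score = mean(group-1 PSI) − mean(group-2 PSI) over detected events.
- **Survival** (`splicescape.survival`) — Kaplan-Meier with log-rank at a
  configurable score cut (median default) and multivariable Cox fits
  (Efron ties, categorical covariates dummy-coded).
- **Pseudobulk single cell** (`splicescape.pseudobulk`) — junction counts
  summed by (patient, cellular state) before PSI estimation, detection
  filters (≥50 signature events per pseudobulk, events in ≥100 pseudobulks,
  with fractional equivalents for small runs), and Cluster-3.0-style
  hierarchical clustering (uncentered correlation, centroid linkage,
  pairwise-complete missing handling).
- **RBP screen** (`splicescape.rbp`) — Spearman correlation of RBP
  expression with AS scores per dataset (BH within dataset), consistency
  across datasets (same sign, q < alpha everywhere), and single-cell
  RBP × event correlation restricted to events detected in >200 cells.
- **Sequence features** (`splicescape.seqfeat`) — GC profiling upstream of
  the 3′ splice site, splice-site strength under three log-odds models
  (WMM / first-order Markov / dinucleotide), IUPAC degenerate motif
  enrichment (Fisher exact, Haldane odds ratios), and de-novo k-mer tables.
- **Synthetic data** (`splicescape.synthetic`) — a fully parameterized
  generator for bulk and single-cell junction counts, survival tables, RBP
  expression and flank sequences with known ground truth (latent two-mode
  continuum, logit-coupled events, exponential survival with a planted
  hazard ratio, planted motifs and GC offsets), used by the recovery tests.
- **I/O and CLI** (`splicescape.io`, `splicescape.cli`) — TSV/FASTA readers
  and writers, MISO-summary and rMATS-JC dialects, JSON-lines run manifests.

## CLI

One executable with a subcommand per stage (`--seed`, `--config YAML`,
`--log-level` are global):

```sh
splicescape --seed 1 simulate --preset bulk --outdir out/sim
splicescape psi --counts out/sim/junction_counts.tsv \
    --events out/sim/events.tsv --outdir out/psi
splicescape filter --psi-matrix out/psi/psi_long.tsv --outdir out/filt
splicescape --seed 1 cluster --psi-matrix out/psi/psi_long.tsv \
    --k 2 --iterations 1000 --outdir out/clust
splicescape --seed 1 signature --psi-matrix out/psi/psi_long.tsv \
    --labels out/clust/cluster_labels.tsv \
    --survival out/sim/samples.tsv --outdir out/sig
splicescape score --psi-matrix out/psi/psi_long.tsv \
    --model out/sig/signature_model.tsv --outdir out/score
splicescape survival --scores out/score/as_scores.tsv \
    --survival out/sim/samples.tsv --covariates age,sex --outdir out/surv
```

`simulate --preset sc|rbp|seq` emit the single-cell, RBP-expression and
flank-sequence datasets; `pseudobulk`, `rbp-screen` and `seqfeat` consume
them (see `splicescape <cmd> --help`).

## Notes

- Detection threshold defaults to 10 informative reads; every threshold in
  the pipeline is exposed in the corresponding config object or CLI flag.
- Internally coordinates are 0-based half-open; sequence handling treats
  U and T as equivalent and is case-insensitive.
- The CI is one-sided at count boundaries (lower bound 0 when I = 0, upper
  bound 1 when S = 0) so the interval always contains the point estimate.
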