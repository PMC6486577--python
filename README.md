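# recseq

Specificity profiling of site-specific DNA recombinases (Cre, evolved Cre
variants, and relatives) from in vitro selection + high-throughput
sequencing experiments, with a selection simulator for ground-truth
validation.

A target site is modelled as two half-sites flanking a constant core where
strand exchange occurs; half-site positions are numbered outward from the
core (loxP: 5–17, right half primed). One half-site is partially
randomized per experiment (79% canonical base, 21% equimolar others), the
library is exposed to recombinase, non-recombined DNA is destroyed, and
pre/post sequencing gives per-position enrichment scores

    r_i = (A_i / B_i) / (alpha_i / beta_i)

where `A_i`/`B_i` are post-selection canonical/non-canonical counts and
`alpha_i`/`beta_i` the pre-selection fractions.

## What's in the package

| module            | contents |
|-------------------|----------|
| `recseq.targets`  | `TargetSite`, center-out numbering, site comparison, bundled loxP/loxLTR/loxBTR |
| `recseq.simlib`   | library/selection/read simulator + closed-form expected-enrichment oracle |
| `recseq.readio`   | FASTQ parsing, exact-core anchored extraction, gap-free ≤6-mismatch filter |
| `recseq.enrich`   | count tables, `r_i`, per-base log2 heat-map matrices, geometric-mean replicate aggregation, full-site assembly |
| `recseq.quality`  | UMI-vs-abundance regression quality score κ and the 1.5/0.5 power thresholds |
| `recseq.stats`    | per-position equal-variance t-tests (Bonferroni), whole-profile Mann–Whitney U on \|residuals\| (exact for pooled n ≤ 12), paired asymmetry test, feature-matrix export |
| `recseq.offtarget`| degenerate motif from positions with enrichment > 2, two-strand genome scanner, non-core mismatch annotation, BED/TSV output |
| `recseq.pipeline` | YAML run config, staged orchestration, JSON reporting, bundled fixtures |

## CLI

```sh
recseq simulate --config sim.yaml --out-dir sim/     # synthetic experiment
recseq run --config run.yaml                         # full analysis
recseq enrich --pre pre.fastq --post post.fastq --site loxP --out profile.tsv
recseq kappa post.fastq --site loxP
recseq motif --left left_agg.tsv --right right_agg.tsv --site loxLTR
recseq scan  --left left_agg.tsv --right right_agg.tsv --site loxLTR \
             --genome genome.fa --bed hits.bed --tsv hits.tsv
recseq fixture cre-selective --out-dir fx/           # mini dataset + snapshot
```

A run config lists one pre-selection library sample and one or more
post-selection replicates:

```yaml
site: loxP
randomized_side: left
umi_length: 10
out_dir: out
samples:
  - {role: pre,  replicate: "1", fastq: pre.fastq}
  - {role: post, replicate: "1", fastq: post1.fastq}
  - {role: post, replicate: "2", fastq: post2.fastq}
```

Outputs: per-replicate and aggregate profile TSVs, `kappa.tsv`, per-sample
filter-report JSONs, and a versioned `report.json`.

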