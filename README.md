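# topnet

Build state-specific gene–gene interaction networks (GGINs) from cohort
expression data, track per-gene degree and clustering coefficient across an
ordered disease-state sequence, and select genes whose network prominence
grows toward the disease state. Selections are filtered by differential
expression, screened for early-detection markers, calibrated with
randomization null models, and scored by hit rate against an annotated
cancer-gene catalog.

A network edge requires both a significant Pearson correlation (p ≤ p0 on
the selected arrays) and a known protein–protein interaction. States with
more arrays than the network size get an ensemble of subsampled networks
whose per-gene statistics are aggregated.

## Layout

- `topnet.io_formats` — TSV/GMT readers and writers, symbol normalization.
- `topnet.synthdata` — multi-state cohort simulator with planted correlated
  modules over a scale-free PPI scaffold (the test substrate).
- `topnet.ggin` — Pearson-edge network construction, subsample ensembles,
  clustering coefficient, structural summaries, per-gene aggregation.
- `topnet.diffexpr` — Welch t / one-way ANOVA contrasts, fold change,
  Benjamini–Hochberg adjustment, permutation FDR, DEG predicates.
- `topnet.trend` — trend selection, DEG-filtered selection, sequence
  combination bookkeeping, hit rate, early-detection marker rules.
- `topnet.nullmodels` — type-1 (intensity scrambling) and type-2 (link
  rewiring) randomizations, null campaigns, add-one permutation p-values.
- `topnet.funcmod` — gene-set module assignment, function–function network
  reduction, link-set overlaps, hypergeometric enrichment.
- `topnet.pipeline` — YAML-driven end-to-end runs with funnel reports and
  config-hash provenance.

## CLI

```bash
topnet simulate --profile paper_shaped --out sim/
topnet build-net --expr sim/expression.tsv --design sim/design.tsv \
    --ppi sim/ppi.tsv --state CRC --p0 0.01 --subsample 8 --reps 100 \
    --seed 7 --out crc/
topnet deg --expr sim/expression.tsv --design sim/design.tsv \
    --contrast Ade:Nor --out deg_ade.tsv
topnet select --sequence Nor,Ade,CRC \
    --gene-stats nor/gene_stats.tsv,ade/gene_stats.tsv,crc/gene_stats.tsv \
    --mode top --out sel/
topnet enrich --selection sel/selected.tsv --gmt go.gmt \
    --universe genes.txt --out enrich.tsv
topnet run --config run.yaml
topnet nulltest --config run.yaml --type type2 --reps 1000 --out null/
```

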