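# k9balance

Differential H3K9me2 / transcript analysis on gene and transposable-element
(TE) count matrices, joint direction classification, up/down balance tests,
TE spatial-association statistics with resampling nulls, chromosome-
compartment enrichment, and proximal-polyadenylation segment-usage
contrasts. A seeded synthetic-data module with planted ground truth lets the
whole pipeline run end-to-end offline.

## Modules

| module | what it does |
| --- | --- |
| `k9balance.genome` | annotation model (genes/TEs/compartment partition), interval arithmetic, GFF3/BED I/O |
| `k9balance.simulate` | seeded generators: annotations with planted TE structure, NB count matrices with planted differential features, polyA coverage tracks |
| `k9balance.differential` | expression filter, median-of-ratios size factors, NB Wald test, BH correction, threshold calling, replicate Spearman QC, K9/H3 paired summary |
| `k9balance.jointclass` | RNA x K9 quadrant classification, 50/50 balance chi-square, percentage summaries |
| `k9balance.teassoc` | TE-bp association curves with resampled ANOVA, nearest-TE distance t-test, superfamily size proportions, randomized Fisher enrichment |
| `k9balance.apa` | coverage CPM/combine/subtract, polyA segment counts, segment-usage contrast, drop-site detection |
| `k9balance.pipeline` / `k9balance.cli` | orchestration, deterministic TSV outputs, run manifest |

## CLI

```sh
# full synthetic pipeline under one seed
k9balance run-all --seed 17 --out out/

# individual stages
k9balance simulate --seed 17 --out sim/
k9balance diff-rna --counts sim/counts_rna.tsv --samples sim/samples_rna.tsv --out diff_rna.tsv
k9balance qc --counts sim/counts_rna.tsv --samples sim/samples_rna.tsv --out qc.tsv
k9balance joint --rna diff_rna.tsv --k9 diff_k9.tsv --out joint.tsv
k9balance balance --calls diff_rna.tsv --categories categories.tsv --out balance.tsv
k9balance te-assoc --annotation sim/annotation.gff3 --out curve.tsv --seed 17
k9balance enrich --annotation sim/annotation.gff3 --partition sim/partition.bed \
    --focal focal_te_ids.txt --out enrichment.tsv --seed 17
k9balance apa --sites sim/polya_sites.tsv \
    --wt-track sim/coverage_apa_WT_rep1.bedgraph --wt-track sim/coverage_apa_WT_rep2.bedgraph \
    --mut-track sim/coverage_apa_mutant_rep1.bedgraph --mut-track sim/coverage_apa_mutant_rep2.bedgraph \
    --out apa_usage.tsv
```

`run-all` writes per-stage TSVs, a `summary.tsv` of headline quantities, and
a `manifest.json` (seed, config hash, versions) that suffices to re-run
bit-identically. Synthetic-run configuration is a flat `key = value` file
(see `k9balance.simulate.SyntheticConfig` for the schema); unknown keys are
rejected.

## Conventions

- Internal coordinates are 0-based half-open; GFF3 I/O is 1-based
  inclusive, BED I/O 0-based half-open.
- Count matrices are TSV with features as rows and sample ids as columns,
  plus a sidecar sample sheet (`sample`, `genotype` in {WT, mutant},
  `assay`, `replicate`).
- PolyA sites are listed 1-based in transcript order (ascending genomic
  coordinates on +, descending on -).

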