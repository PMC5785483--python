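# oralmia

Oral-microbiome group-comparison toolkit: a tested, reusable implementation
of a two-group (ASD vs control), two-habitat (saliva vs dental plaque) 16S
OTU-table analysis — diversity profiling, differential-OTU screening,
co-occurrence networks, random-forest marker selection, and a composite
"microbial index" diagnostic score with exhaustive panel search and ROC
evaluation — exercised end to end on a built-in synthetic study generator,
so no sequencing data download is required.

## Modules

| module              | what it does |
|---------------------|--------------|
| `oralmia.synthdata` | Dirichlet-multinomial study generator: habitat-specific compositions, spiked differential OTUs with known directions, latent-factor co-occurrence blocks, clinical covariates correlated with marker load, random phylogenies |
| `oralmia.io_tables` | strict TSV/Newick/GraphML readers and writers; `OtuTable`, `SampleRecord`, `PhyloTree`, `DistanceMatrix` containers |
| `oralmia.alphadiv`  | rarefaction, ACE, Shannon, Shannon evenness, Good's coverage, rarefaction curves, Welch group comparison |
| `oralmia.betadiv`   | unweighted/weighted UniFrac, taxonomic aggregation, PCoA, one-factor PERMANOVA |
| `oralmia.difftax`   | relative abundance, Wilcoxon rank-sum + Benjamini–Hochberg FDR screening, clinical Spearman correlation with cluster ordering |
| `oralmia.network`   | thresholded Spearman co-occurrence networks, graph summaries, Cytoscape-ready exports |
| `oralmia.markers`   | random-forest marker ranking, 10-fold CV marker-count selection, MIA scoring, (m, n) grid / power-set panel enumeration, ROC/AUC, Youden cut-off, honest train/test evaluation |
| `oralmia.pipeline`  | `run_all`: simulate → alpha → beta → diff → network → markers → mia with a hash manifest for reproducibility |

## CLI

Every stage is a subcommand of `oralmia`:

```sh
oralmia simulate --out-dir run --seed 1                # synthetic study
oralmia alpha --table run/table.tsv --metadata run/metadata.tsv \
    --seed 1 --out run/alpha.tsv
oralmia beta --table run/table.tsv --metadata run/metadata.tsv \
    --tree run/tree.nwk --metric w-unifrac --out-dir run
oralmia diff --table run/table.tsv --metadata run/metadata.tsv \
    --rank otu --out run/diff.tsv
oralmia network --table run/table.tsv --metadata run/metadata.tsv \
    --diff-results run/diff.tsv --group control --habitat saliva \
    --out-prefix run/net_control_saliva
oralmia markers --table run/table.tsv --metadata run/metadata.tsv \
    --habitat saliva --out-prefix run/saliva
oralmia mia --table run/table.tsv --metadata run/metadata.tsv \
    --habitat saliva --mode grid --scale counts --out-prefix run/mia_saliva
oralmia predict --table run/table.tsv --asd-otus OTU001,OTU002 \
    --control-otus OTU003 --cutoff -480 --out run/pred.tsv
oralmia run-all --out-dir run --seed 1                 # all 7 stages
```

`run-all` also accepts a flat `key = value` config file via `--config`
(flags override file values) and writes `manifest.json` recording each
stage's parameters and output hashes; identical configs reproduce identical
hashes.

## Notes

- MIA scores default to raw per-sample read counts (`scale="counts"`); a
  relative-abundance mode is available everywhere via `--scale relative`.
- UniFrac operates on OTU-level tables (the tree's leaves); `aggregate`
  provides phylum→species roll-ups for the differential screen.
- All stochastic steps (generator, rarefaction, PERMANOVA permutations,
  forests, CV folds) are seed-deterministic.
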