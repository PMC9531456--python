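# chromark

Analysis toolkit for sparse-background chromatin-mark coverage tracks
(CUT&Tag-style bedGraphs): SEACR-style peak calling, overlap-enrichment
statistics, combinatorial promoter/enhancer marking classification with
expression integration, multivariate Bernoulli-HMM chromatin-state
discovery (multi-mark per tissue, or one mark across tissues), distal
enhancer-to-gene linkage, and pairwise differential marking — together
with a synthetic multi-tissue data generator that plants known
promoter/enhancer occupancy structure for end-to-end recovery testing.

## Modules

| module | what it does |
|---|---|
| `chromark.io_formats` | bedGraph/BED/TSV I/O, strict 0-based half-open intervals, merged-set bp arithmetic (`overlap_bp`) |
| `chromark.synthetic_data` | toy genome + coverage + expression generator with ground-truth tables |
| `chromark.peaks` | replicate merging (mean over union breakpoints), stringent top-fraction AUC peak calling, blacklist filtering, union peak lists, region/tile quantification, CPM/RPKM/log2 normalization |
| `chromark.annotate` | one-label-per-peak feature annotation, `feature_fold_enrichment` (overlap·genome/(peaks·feature)), `pairwise_set_enrichment` (overlap/(setA·setB)), element coverage fractions, TSS-distance profiles |
| `chromark.chromstate` | 200-bp Poisson-tail binarization, Baum–Welch Bernoulli HMM, posterior-max segmentation (Viterbi optional), state/element enrichment, emission-correlation model comparison |
| `chromark.integrate` | element×mark marking tables, Venn cells, mark-combination groups, Mann-Whitney group comparisons, Pearson/Spearman correlation, top-feature RMS MDS, nearest-non-overlapping-promoter linkage |
| `chromark.differential` | conditional exact count test (binomial/NB with moment dispersion), BH correction, change–change correlation, per-class fold-change comparisons |

## CLI

All stages are exposed under a single `chromark` entry point:

```sh
# synthetic dataset (bedGraphs, BED element sets, gene models, truth tables)
chromark simulate --outdir data --seed 5            # optional --config cfg.yaml

# merged-replicate stringent peak calling (top 1% of blocks by AUC)
chromark callpeaks --bedgraph data/tissue1_H3K18la_rep1.bedgraph \
    --bedgraph data/tissue1_H3K18la_rep2.bedgraph \
    --chrom-sizes data/chrom.sizes --top 0.01 --out peaks.bed

# feature annotation and TSS distances
chromark annotate --peaks peaks.bed --genes data/genes.tsv \
    --cgi data/cgi.bed --chrom-sizes data/chrom.sizes --out annot.tsv

# quantification over regions or genome-wide tiles
chromark quantify --track la data/tissue1_H3K18la_rep1.bedgraph \
    --tile 3000 --chrom-sizes data/chrom.sizes --normalize log2CPM --out q.tsv

# chromatin states
chromark chromstate binarize --track H3K18la ... --chrom-sizes ... --out bin.tsv
chromark chromstate learn --bin bin.tsv --K 7 --seed 1 --out model.json
chromark chromstate segment --bin bin.tsv --model model.json --out seg.bed
chromark chromstate enrich --bin bin.tsv --model model.json \
    --elements planted data/elements.bed --out enrichment.tsv
chromark chromstate compare --candidate m7.json --reference m20.json --out cmp.tsv

# integration & differential
chromark integrate venn --elements data/elements.bed \
    --peaks H3K18la la.bed --peaks H3K27ac ac.bed --out venn.tsv
chromark integrate link --dels dels.bed --genes data/genes.tsv \
    --chrom-sizes data/chrom.sizes --out links.tsv
chromark integrate mds --matrix q.tsv --out mds.tsv
chromark diff --a condA_counts.tsv --b condB_counts.tsv \
    --regions union.bed --fdr 0.05 --minlfc 0.5 --out diff.tsv
```

`cfg.yaml` for `simulate` may override any `SyntheticConfig` field, e.g.

```yaml
n_chroms: 3
chrom_length: 1000000
n_tissues: 3
marks: [H3K18la, H3K27ac, H3K4me3, H3K27me3]
enrichment_fold: 10
background_rate: 0.5
```

## Acceptance

The acceptance criteria are property- and simulation-based (peak-caller
recovery of planted elements, Poisson-tail binarization vs brute-force
oracle, HMM posteriors vs exhaustive path enumeration, planted-state and
group-ordering recovery, differential null calibration, linkage vs
exhaustive scan, full CLI end-to-end run) and live in
`tests/test_acceptance.py`.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a compact simulate → peaks → chromatin-states → differential
pipeline and writes the per-target value report (empty: this artifact
defines no numeric acceptance targets; all checks are the tests above).
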