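# stressnet

Cross-species, time-resolved stress-response network analysis at desk scale.
The package implements the full analysis chain as reusable, tested modules,
plus a seeded synthetic-data generator so every stage runs without any
external downloads:

| module | role |
| --- | --- |
| `stressnet.synthdata` | seeded multi-species datasets: sample design (29 condition-time combos, triplicates, 0 h in sextuplicate), orthogroup (HOG) tables, GP-shaped trajectory archetypes, negative-binomial counts, lagged VAR benchmark series, metabolite channels |
| `stressnet.preprocess` | CPM, expression filter (CPM > 10 in ≥ 3 samples), smooth group-aware quantile normalization, log-CPM, PCA overview |
| `stressnet.diffexpr` | treatment-vs-matched-control contrasts, empirical-Bayes moderated t, BH adjustment, DEG calls, hypergeometric over-representation analysis |
| `stressnet.coexpr` | signed weighted co-expression networks: biweight midcorrelation, soft-threshold selection with scale-free fit, signed TOM, module detection/merging, eigengenes, module-trait correlation, top-20 hubs |
| `stressnet.traject` | Dirichlet-process Gaussian-process mixture clustering of log2FC time courses with posterior co-clustering and tightness filtering |
| `stressnet.crossmap` | projection of clusters to HOG space, Jaccard distance matrices, conserved-cluster calls across species |
| `stressnet.grn` | sliding-window lagged random-forest causal inference with mean-mean rank aggregation and top-fraction edge retention |
| `stressnet.conserve` | HOG-level conserved network: cross-species intersection, temporal-conservation filter, degree/HITS hub metrics, scale-free check, rank stability, printed-precision count reports |

## CLI

Each stage is exposed under a single `stressnet` entry point:

```sh
stressnet synth --config cfg.yaml --seed 3 --outdir data/
stressnet preprocess --counts data/counts_sp1.tsv --design data/design.tsv \
    --group-by condition --out expr_sp1.tsv
stressnet de --expr expr_sp1.tsv --design data/design.tsv --annot go.tsv --out de_sp1.tsv
stressnet coexpr --expr expr_sp1.tsv --traits data/metabolites.tsv --beta 20 --outdir wgcna_sp1/
stressnet dpgp --trajectories traj_heat_sp1.tsv --alpha 1 --iters 500 --seed 3 --outdir dpgp_sp1/
stressnet crossmap --clusters sp1 dpgp_sp1/partition.tsv --clusters sp2 dpgp_sp2/partition.tsv \
    --hogs data/hogs.tsv --topk 50 --outdir crossmap/
stressnet grn --series series_sp1.tsv --window 4 --max-lag 1 --trees 500 --seed 3 --out edges_sp1.tsv
stressnet conserve --edges sp1 edges_sp1.tsv --edges sp2 edges_sp2.tsv --edges sp3 edges_sp3.tsv \
    --hogs data/hogs.tsv --dpgp-conserved tight_members.tsv --outdir conserved/
```

All inputs and outputs are plain TSV/JSON; matrices carry a header row of
sample ids and a first column of gene ids.

## Notes

- All randomness is driven by explicit seeds; identical configuration and
  seed give byte-identical outputs.
- Tree-cut, conserved-cluster and hub-ranking strategies are pluggable; see
  module docstrings for the defaults and their rationale.
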