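# seednet

Comparative seed-network analysis of time-course gene expression data.

A small, literature-curated network of fly retinal-determination genes is
projected onto mouse homologs, and multiple developmental expression
datasets are screened for correlation support: pairs of projected seed
genes whose Spearman rank correlation passes an absolute threshold form the
*extracted seed network* (ESN). Each dataset is then queried for genes
correlated with individual ESN seeds, lists are aggregated across seeds and
datasets, and genes correlated with at least three distinct seeds become
candidates. A hypergeometric upper-tail (Fisher's exact, one-sided) test
checks annotation over-representation within the candidate list. A
synthetic-data generator with planted signed co-expression structure makes
the whole pipeline testable without any external datasets.

## Layout

| module                 | responsibility |
|------------------------|----------------|
| `seednet.datasets`     | TSV readers/writers, symbol canonicalization, domain types |
| `seednet.correlation`  | tie-aware Spearman rho, thresholded pairwise screening |
| `seednet.esn`          | homolog projection, ESN extraction, fly-edge conservation report |
| `seednet.candidates`   | per-seed correlate lists, ≥k-seed aggregation, signature groups |
| `seednet.enrichment`   | hypergeometric upper tail from first principles (log-gamma) |
| `seednet.simulate`     | synthetic multi-dataset studies with a ground-truth manifest |
| `seednet.cli`          | `seednet simulate / extract / query / enrich` |

Packaged reference inputs (`seednet/data/`): the fly→mouse homolog table, a
synonym table (e.g. `Sdccag33` → `Tshz1`), and a replaceable default fly
seed-network edge list.

## CLI walkthrough

```sh
# 1. generate a synthetic study (4 datasets + truth manifest)
seednet simulate --config sim.yaml --out simdir/

# 2. project the fly network and extract the correlated seed network
seednet extract \
    --datasets simdir/dataset_D1.tsv --datasets simdir/dataset_D2.tsv \
    --homologs simdir/homologs.tsv --seed-network simdir/seed_network.tsv \
    --threshold 0.65 --min-pairs 4 --out esn/

# 3. query for candidates correlated with >= 3 ESN seeds
seednet query --esn esn/ \
    --datasets simdir/dataset_D1.tsv --datasets simdir/dataset_D2.tsv \
    --threshold 0.65 --min-seeds 3 --out candidates.tsv

# 4. over-representation of an annotation term among candidates
seednet enrich --candidates candidates.tsv \
    --term-counts 550 8544 --observed 7
```

`extract` writes `presence.tsv` (per-seed/per-dataset status:
`present_correlated`, `present_uncorrelated`, `absent`), `esn_edges.tsv`,
a Cytoscape-compatible `esn.sif` (+ score TSV), and `conservation.tsv`
(which fly edges are supported by a mouse edge, with sign agreement).

Expression matrices are plain TSV: header row of time-point labels, first
column gene symbols, empty cells for missing values. Duplicate symbol rows
are collapsed by per-condition median; symbol matching is case-insensitive
with a synonym table.

## Notes

- Spearman rho is Pearson-on-average-ranks over pairwise-complete
  observations (correct under ties); pairs with fewer than `--min-pairs`
  complete observations or zero rank variance are *undefined* and never
  create or suppress edges.
- The threshold comparison is inclusive (|rho| ≥ 0.65) by default;
  `--strict-threshold` switches to strict.
- Candidate counting is over *distinct* seeds across the union of datasets;
  positive and negative correlations both qualify.
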