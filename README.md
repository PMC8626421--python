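# phyloconcord

A toolkit for quantifying gene-tree/species-tree discordance and testing
polyploidy scenarios:

- **tree model** (`phyloconcord.tree`) — newick parsing/writing, splits
  (bipartitions), induced quartet topologies; support values normalised to
  a [0, 100] scale.
- **MSC simulator** (`phyloconcord.msc`) — gene-tree simulation under the
  multispecies coalescent within a species tree in coalescent units,
  including the near-zero-theta "no ILS" baseline rescaling.
- **concordance statistics** (`phyloconcord.concordance`) — quartet
  frequency tables over all four-taxon subsets, per-branch quartet
  supports (q1/q2/q3), coalescent-unit estimation from q1, OLS agreement
  between frequency tables, chi-square tests on minor-topology counts,
  and split support classification (strongly/weakly supported/rejected
  with low-support-edge contraction at a 75% threshold).
- **theta pipeline** (`phyloconcord.theta`) — per-branch theta
  (mutation-unit length / coalescent-unit length) and the end-to-end ILS
  assessment comparing empirical gene trees against with-ILS and no-ILS
  simulations.
- **WGD tests** (`phyloconcord.wgd`) — shared-vs-independent
  whole-genome-duplication classification of copy-labelled collinear gene
  trees (2+2 and 3+3 copies), per-block median Ks, Gaussian-mixture Ks
  peak fitting by EM, and LTR insertion-time dating (T = K/2r).
- **synthetic data** (`phyloconcord.synthetic`) — generators with known
  ground truth for every input the pipeline consumes.

## CLI

The console script `phyloconcord` groups the pipeline stages; every
randomised command takes `--seed` and is byte-reproducible.

```sh
# generate a synthetic MSC scenario (species trees + gene trees + ground truth)
phyloconcord synth --scenario msc --n 20000 --seed 1 --n-taxa 7 --out demo/

# simulate gene trees under the MSC
phyloconcord simulate --species-tree demo/species_cu.nwk --n 20000 --seed 2 --out sim.nwk

# quartet-topology counts for all four-taxon subsets
phyloconcord quartets --gene-trees sim.nwk --out quartets.tsv

# q1/q2/q3 and estimated coalescent length per internal branch
phyloconcord branch-support --gene-trees sim.nwk --species-tree demo/species_cu.nwk --out support.tsv

# regression agreement between two quartet tables
phyloconcord compare --table-a quartets.tsv --table-b other.tsv --out agreement.json

# full ILS assessment (simulations, regressions, per-branch chi-square, theta table)
phyloconcord ils-report --empirical demo/gene_trees.nwk \
    --mu-tree demo/species_mu.nwk --cu-tree demo/species_cu.nwk \
    --n 20000 --seed 3 --out report/

# WGD classification of copy-labelled collinear gene trees
phyloconcord wgd-classify --trees copy_trees.nwk --species-a A --species-b B --out wgd.json

# Ks mixture peak fit and LTR dating
phyloconcord ks-fit --ks ks.tsv --k 2 --out ksfit.json
phyloconcord ltr-time --k 0.0076
```

## File formats

- Trees: newick, one tree per line; `#`-prefixed lines are comments.
  Numeric internal labels are read as branch supports (posteriors in
  (0, 1] are rescaled to percent).
- Quartet tables: TSV with columns `subset` (taxa joined by `|`), `n1`,
  `n2`, `n3`, `unresolved`, `missing`.
- Ks input: TSV with columns `block_id`, `gene1`, `gene2`, `ks`.
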