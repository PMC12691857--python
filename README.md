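# cnmnet

Co-expression modules and multiplex-heterogeneous network propagation for
centronuclear myopathy (CNM) multi-omics.

CNMs are rare inherited muscle disorders (MTM1, DNM2, BIN1 mutations) studied
in mouse models that can be rescued by cross-acting therapies. This package
implements the two computational arms used to dissect their pathomechanisms:

1. **Weighted gene co-expression network analysis (WGCNA-style).** From bulk
   RNA-seq counts of multi-cohort mouse experiments: gene filtering (>10
   reads in ≥90% of samples), median-of-ratios normalization, unsigned
   soft-threshold adjacency `a_ij = |cor(x_i, x_j)|^β` (β = 12), topological
   overlap `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
   average-linkage clustering with dynamic-cut-style module detection,
   eigengene merging at dissimilarity < 0.25, module–trait Pearson
   correlation with Student-t p-values and Bonferroni correction over the
   traits, and classification of modules as *beneficial* (positively
   correlated with muscle mass / force / hanging time, negatively with
   central nuclei / abnormal mitochondria / small fibers) or *pathogenic*
   (the mirror pattern).
2. **Random walk with restart (RWR) on a multiplex-heterogeneous network.**
   Genes (5 layers: PPI, complex and pathway co-membership, transcriptomic
   and proteomic co-expression), metabolites (2 layers), a directed reaction
   monoplex, a phenotype-ontology DAG, and tissue nodes, joined by 8
   bipartites. The walker restarts at the seeds with probability r = 0.7 and
   otherwise moves with uniform layer / multiplex-jump probabilities. On top
   of the walk: a resampling null that detects *nonspecific hubs* (nodes in
   the top-50 of >5% of 1000 random-gene-seeded walks), hub removal, and
   joint gene+phenotype seed queries with shared/specific overlap tables.

Both arms are driven end to end by synthetic data generators that return
ground truth (planted modules, group-averaged traits, planted hubs), so every
statistical claim in the test suite is checked against a known answer.

## Worked example

```python
import cnmnet
from cnmnet.simulate import ExpressionSimSpec, simulate_expression_with_traits

data = simulate_expression_with_traits(ExpressionSimSpec(rng_seed=0))
res = cnmnet.WGCNA(data.counts, data.traits).fit()
print(res.summary())
```

prints

```
Weighted co-expression network fit
========================================
features (filtered): 399
samples:             24
soft power:          12.0
modules:             3 (+ grey)

module            size  class
grey               250  -
turquoise           50  beneficial
blue                50  unclassified
brown               49  beneficial

significant module-trait correlations (p_adj < 0.05):
  turquoise     body_mass                 r=+0.73  p_adj=4.20e-04
  turquoise     relative_maximal_force    r=+0.69  p_adj=1.46e-03
  turquoise     normalized_ta_mass        r=+0.63  p_adj=7.10e-03
  turquoise     pct_central_nuclei        r=-0.58  p_adj=2.05e-02
  brown         pct_abnormal_mitochondria r=-0.56  p_adj=2.86e-02
```

The three 50-gene planted modules are recovered exactly (adjusted Rand index
1.0 against the generator's ground truth); the 250 background genes stay
grey. The turquoise module tracks the healthy-muscle axis: it correlates
positively with mass and force and negatively with the fraction of
centrally-nucleated fibers, so it is classified beneficial.

On the network side:

```python
spec = cnmnet.table_shaped_network_spec(rng_seed=0, hubs=(cnmnet.HubSpec("genes", 0.5),))
net, hubs = cnmnet.simulate_multilayer(spec)
res = cnmnet.joint_seed_query(net, gene_seed="g010", phenotype_seed="hp005", top_n=5)
print(res.metabolites)
```

```
      node     score
rank
1     m003  0.038543
2     m037  0.001219
3     m008  0.001110
4     m006  0.001071
5     m001  0.000777
```

`m003` is the metabolite bridging the gene and phenotype seeds through the
bipartites, and it dominates the metabolite ranking — the shared-neighbor
signal the joint-seed query is designed to surface.

The same functionality is available from the shell:

```bash
cnm-net simulate network --seed 3 --out net/
cnm-net summarize net/manifest.yaml
cnm-net hubscan --manifest net/manifest.yaml --n 1000 --seed 42 --out hubs/
cnm-net explore --manifest net/manifest.yaml --gene g010 --phenotype hp005 --out q1/
cnm-net run pipeline.yaml          # config-driven multi-stage run
```

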