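# mixdag

DAG structure learning from **mixed** observational data — tables in which
some columns are continuous measurements (gene or protein expression,
metabolite levels, clinical covariates) and others are categorical (disease
status, genotypes, batch labels). Most DAG learners assume every variable
shares one distributional family; `mixdag` models each variable by its own
conditional family, which lets expression, phenotypes, and SNPs live in one
causal graph, with SNPs optionally constrained to be causes only.

## Method

The estimator is a hybrid of neighborhood selection, constraint-based
pruning, and score-based orientation:

1. **Markov blankets (mixed graphical model).** Assuming the joint
   distribution is a pairwise Markov random field, every node's conditional
   distribution given the rest is gaussian (continuous) or multinomial
   (categorical). Each node *j* is regressed on all others by an
   L1-penalized GLM,
   `min_beta  -loglik(beta_j) + lambda_j * ||beta_j||_1`,
   with `lambda_j` selected by the extended BIC
   `EBIC_gamma = -2 loglik + k log n + 2 gamma k log(d-1)` (k = number of
   selected coefficients). Nodes that select each other are joined, giving
   an undirected graph that contains the true skeleton plus moralization
   edges between co-parents.
2. **Skeleton (permutation CI test + PC-stable).** For mixed pairs,
   conditional independence is tested by regressing both variables on the
   conditioning set (ordinary residuals for continuous targets, summed
   multinomial-logit Pearson residuals for categorical targets), correlating
   the residuals, and comparing against B permutations of one residual
   vector: `p = (1 + #{|rho_b| >= |rho|}) / (B + 1)`; independence is
   declared when `p > alpha`. A modified PC-stable loop restricted to the
   MGM's adjacencies removes separable edges and records each certifying
   conditioning set (the d-separation set).
3. **Orientation (BIC hill climbing).** Starting from an empty directed
   graph, greedy add/delete/reverse moves restricted to skeleton pairs
   minimize the decomposable score `sum_j [-2 loglik_j + k_j log n]`,
   rejecting cycles and constraint violations, until no move improves.

A simulator reproducing the standard benchmark protocol (random DAGs,
structural-equation sampling with mixed node types) and
sensitivity/specificity/FDR edge-recovery metrics are included.

## Worked example

```python
import mixdag as m

# simulate a 20-node mixed dataset (10% categorical, 4 levels each)
cfg = m.ScenarioConfig(n=500, d=20, n_edges=20, frac_categorical=0.10, seed=42)
truth, data = m.simulate_scenario(cfg)

est = m.MixedDAG(random_state=1).fit(data)
print(len(est.mgm_.graph_.edges), len(est.skeleton_.graph.edges),
      len(est.graph_.directed_edges))

rep = m.skeleton_metrics(est.skeleton_.graph, truth)
print(rep.sensitivity, rep.specificity, rep.fdr)
rep = m.dag_metrics(est.graph_, truth)
print(rep.sensitivity, rep.specificity, rep.fdr)
```

prints

```
79 20 20
1.0 1.0 0.0
0.9 1.0 0.1
```

— the nodewise regressions propose 79 candidate edges, the permutation
CI test prunes them to exactly the 20 true skeleton edges (sensitivity 1,
FDR 0), and hill climbing orients 18 of 20 correctly (DAG-level sensitivity
0.9; the two misses are directionally ambiguous pairs, which cost both
sensitivity and FDR but not specificity).

The same pipeline is available from the shell:

```bash
mixdag simulate --n 500 --d 20 --edges 20 --frac-cat 0.1 --seed 42 \
    --out data.csv --truth truth.tsv --types-out types.yaml
mixdag run --data data.csv --types types.yaml --out-dir fit/
mixdag evaluate --estimated fit/dag.tsv --truth truth.tsv --level dag
```

Real data enter through `load_mixed_dataset(path, types)` plus an optional
constraints file (`source_only:` nodes, e.g. SNPs, never receive edges).

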