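# Methods

## Model and assumptions

`mixdag` estimates a directed acyclic graph over d variables from n i.i.d.
cross-sectional observations, where each variable is declared continuous or
categorical (unordered, L_j >= 2 levels). The working assumption is that the
joint distribution is a pairwise Markov random field over the mixed
variables and is faithful to a DAG: every conditional independence in the
distribution corresponds to d-separation in the graph. Under the pairwise
MRF, each node's conditional distribution given all others is gaussian
(continuous nodes) or multinomial (categorical nodes), which is what makes
nodewise GLM estimation coherent for mixed data.

Causal interpretation of the output requires the usual caveats: no
unmeasured confounding, no selection bias, and orientation is only
identifiable up to Markov equivalence unless asymmetries (v-structures,
mixed-type conditionals, constraints) break ties.

## Stage 1 — Markov blankets by nodewise penalized GLMs

Each node j is regressed on all other nodes. Continuous predictors are
standardized (mean 0, sd 1, ddof=0) inside the solver, because L1 paths are
scale-dependent; coefficients are reported back on the original scale.
Categorical predictors enter as L-1 reference-coded indicators (level 1 is
the reference, levels coded in first-appearance order of labels), and the
indicators are penalized individually (plain L1, no group penalty). The
loss is the sum-form negative log-likelihood, so for a gaussian node the
penalized problem is `1/2 ||y - Xb||^2 + lambda ||b||_1` (profile sigma^2)
and, with a single standardized predictor, the solution is exactly
`soft_threshold(OLS slope, lambda/n)`. Gaussian fits use scikit-learn's
coordinate descent (`alpha = lambda/n`); multinomial fits use an in-package
FISTA proximal-gradient solver with reference coding (the level-1 weight
vector is fixed at zero so coefficients are identified; the symmetric
softmax parameterization used by generic logistic solvers would make the
EBIC/BIC coefficient counting ambiguous).

The penalty is chosen per node over a path of 50 log-spaced values from
lambda_max (the smallest penalty with an empty active set, computed from
the null-model gradient) down to 0.01 * lambda_max, warm-started, by
minimizing

    EBIC_gamma = -2 loglik + k log n + 2 gamma k log(d-1),

where k counts nonzero non-intercept coefficients (multinomial: across all
level blocks) and the log-likelihood is the unpenalized value at the fitted
coefficients. Ties go to the larger penalty (sparser model). `gamma = 0.5`
by default — the established middle ground between BIC (gamma=0) and the
most conservative choice (gamma=1) for d comparable to n; exposed as a
parameter. With gamma=0 the criterion coincides exactly with the
orientation BIC.

Node i and j are joined when either nodewise regression selects the other
(OR rule; a categorical predictor counts as selected when any of its
indicator coefficients is nonzero). The OR rule preserves Markov-blanket
supersets, which is what the next stage needs; the AND rule is available
(`rule="and"`). Coefficients below 1e-8 in magnitude after convergence are
treated as exact zeros.

## Stage 2 — skeleton via permutation conditional-independence testing

The MGM contains every skeleton edge plus moralization edges between
co-parents of v-structures; those are exactly the edges that some
conditioning set renders independent. For mixed pairs, zero partial
correlation is not equivalent to conditional independence, so the test is
built from residuals and a permutation null:

* each of X_j, X_l is regressed on the conditioning set X_K (intercept-only
  when K is empty): ordinary residuals for continuous targets; for a
  categorical target, the summed Pearson residual of a reference-coded
  multinomial logit, `r_i = sum_k (x_ik - mu_ik)/sqrt(mu_ik(1-mu_ik))` over
  the L-1 indicators (the logistic Pearson residual when L=2);
* the statistic is the Pearson correlation rho of the two residual vectors;
* the second residual vector is permuted B times (permuting one vector is
  sufficient for exchangeability under the null), and

      p = (1 + #{b : |rho_b| >= |rho|}) / (B + 1).

The p-value is two-sided with an add-one correction. This is worth flagging
prominently: a one-sided, uncorrected count of `rho > rho_b` paired with an
"independent if p is large" rule is internally inconsistent — a strongly
*dependent* pair would produce p near 1 and be declared independent — so
the standard two-sided, add-one form is used; it keeps p strictly positive
and declares independence iff `p > alpha`. Because permutation preserves
the permuted vector's mean and norm, the B correlations are computed as a
single gather-and-matvec, so a test costs two GLM fits plus O(Bn).

Pruning follows PC-stable restricted to MGM edges: for conditioning-set
sizes s = 0, 1, ..., max_cond_size, with adjacency sets frozen at the start
of each level, every surviving edge {j, l} is tested against all size-s
subsets of adj(j)\{l} and adj(l)\{j}, enumerated in lexicographic order;
the first subset certifying independence removes the edge and is recorded
as its d-separation set. Per-test permutation seeds are derived by hashing
(global seed, sorted pair, sorted subset), and the permuted member of the
pair is the lexicographically larger name, so the result is invariant to
input column order. Residuals are cached by (target, conditioning set).

Defaults: `alpha = 0.05`; `B = 200` permutations (p-value resolution
1/201, comfortably below alpha while keeping the PC loop affordable);
`max_cond_size = 3` (the frozen MGM adjacencies already bound the subsets;
larger sets add cost and lose power at moderate n).

## Stage 3 — orientation by BIC hill climbing

Node j with parent set Pa(j) is scored by the unpenalized GLM BIC
`-2 loglik_j + k_j log n`, with k_j counting non-intercept coefficients
(indicator columns individually, multinomial across level blocks; the
gaussian variance is not counted — only penalized-coefficient analogues
are, so offsets cancel in comparisons). The overall score decomposes over
nodes, so a move rescored only its endpoints; incremental and full
recomputation agree to 1e-9.

Search starts from the empty graph and repeatedly applies the single legal
move — add j->k or k->j on a skeleton pair with no current edge, delete an
existing edge, or reverse one (scored jointly as a single move rescoring
both endpoints) — with the largest strict BIC decrease, skipping moves that
create a directed cycle (incremental DFS reachability check) or violate
constraints (no edge into a `source_only` node; no `forbidden` ordered
pair). It stops when no move strictly decreases the score, so the trace is
strictly monotone and the endpoint is a verified local optimum.

**Tie-breaking.** Markov-equivalent orientations of the same pair have
mathematically identical single-move scores (for two gaussian nodes both
add directions change the score by n log(1 - r^2)), so "largest decrease"
alone is decided by floating-point noise, and a naive deterministic
tie-break can walk into a score plateau: from the fork W->X, W->Z no
strictly improving single move leads to the collider X->W<-Z even when the
collider scores far better. Ties within a relative 1e-6 are therefore
resolved by a deterministic one-step lookahead: each tied move is applied
virtually and the one whose best follow-up move descends furthest wins;
remaining ties break by move type (add < delete < reverse) then
lexicographic edge. This keeps the search deterministic and strictly
descending while letting it commit to colliders. A literal nodewise sweep
(`search_mode="nodewise_sweep"`) is available for fidelity experiments.

Perfect separation in a multinomial fit (diverging weights) falls back to a
ridge-stabilized fit with penalty 1e-6 and a warning; collinear design
columns are dropped via column-pivoted QR and excluded from the parameter
count, so duplicated parents leave scores unchanged.

## Simulator

The benchmark generator draws a uniformly random topological order, then
n_edges distinct order-respecting edges uniformly without replacement
(acyclic by construction, exact edge count); a uniformly random subset of
round(frac * d) nodes is marked categorical with L levels. Sampling in
topological order: parentless continuous ~ N(0,1); parentless categorical
~ uniform on {1..L}; continuous with parents ~ N(sum of parent values, 1);
categorical with parents ~ Multinomial(1, p) with p_l proportional to
exp(l * parent sum), computed with log-sum-exp stabilization. Categorical
parents contribute their integer level codes to children's sums — note this
imposes an artificial ordering on nominally unordered levels; it is part of
the generative protocol being emulated, not a modeling recommendation.
Each node draws from its own RNG substream keyed by node index, so runs are
bit-reproducible and adding nodes does not shift earlier nodes' draws.

The eight scenario presets vary sample size (100/1000), node count
(100/500), edge count (100/500) and categorical fraction (10%/20%); the
presets are the even-parity half fraction of the full 2^4 grid, which
includes both the all-low and all-high corners.

What the simulator does *not* emulate about real omics data: heavy-tailed
or skewed expression, measurement error, unobserved confounders, linkage
between SNPs, non-additive effects, and ordered categorical traits. Passing
recovery tests on this generator demonstrates correctness of the algorithm
under its own assumptions, not performance on any particular biological
dataset.

## Evaluation metrics

Skeleton level: sensitivity = |est ∩ true skeleton| / |true skeleton|,
specificity over unordered null pairs, FDR = |est − true| / |est|. DAG
level: sensitivity and FDR require direction agreement and exclude
undetermined edges from credit; specificity is computed on unordered pairs,
so a directionally wrong edge costs sensitivity and FDR but not
specificity. FDR with zero estimated edges is defined as 0 (no discoveries,
no false discoveries). Undetermined edge marks exist only to score
partially directed output of other methods; the pipeline itself always
returns a fully directed acyclic graph. A type-blind comparator (the
identical pipeline with categorical columns re-declared continuous) is
built in for contrast experiments.

## Problem sizes used by the test suite and acceptance script

Chosen to make each statistical check resolvable in minutes on one CPU:
CI-test calibration and power use n = 200 with B = 200 (resp. 100) over 500
replicates; Fisher-z agreement uses 40 six-node all-continuous datasets at
n = 500 with 8 (pair, |K| <= 2) probes each; moralization/collider recovery
uses 100 three-node datasets at n = 1000; hill-climb optimality uses 100
three-node instances at n = 500 against exhaustive enumeration (3^edges
orientations); the type-aware vs type-blind contrast uses d = 20, 20 edges,
n = 500, 10% categorical, 25 paired replicates.

## Known limitations

* Orientation within a Markov equivalence class is unidentifiable from the
  score; on all-gaussian subgraphs roughly the equivalence-class share of
  edges is oriented arbitrarily (deterministically, but without
  information). The type-aware advantage concentrates on edges incident to
  categorical nodes, whose conditional families are directionally
  asymmetric.
* The permutation test uses estimated residuals, which makes it very
  slightly anti-conservative at moderate n (the residual vectors live in an
  (n - |K| - 1)-dimensional subspace while permutations explore the full
  space); empirically the type-I error at alpha = 0.05, n = 200 is close to
  nominal, and the acceptance script recomputes it.
* The greedy search has no restarts; it is deterministic given the data and
  can in principle terminate at a non-global local optimum on larger
  graphs.
* Fitted multinomial probabilities are clamped to [1e-8, 1 - 1e-8] for the
  Pearson residuals; near-deterministic categorical variables (common deep
  in the simulated DAGs, where parent sums are large) produce heavy-tailed
  residuals and reduced CI-test power on their edges.
* All categorical variables are treated as unordered; ordinal structure is
  neither exploited in estimation nor preserved in evaluation.
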