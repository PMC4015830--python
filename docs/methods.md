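# Methods

## Model and procedure

`modwalk` searches a biological interaction network for communities of
interacting genes whose joint differential expression is larger than
expected under random sampling, and evaluates those communities against a
curated gene-label list. The procedure is semi-supervised: the phenotype
enters only through edge weights derived from per-gene fold changes, while
community formation itself is driven by the graph structure via a short
random walk.

### Random walk and distances

For a weighted adjacency A, one walk step moves i → j with probability
P_ij = A_ij / d(i), d(i) = Σ_j A_ij. Rows of Pᵗ summarize where a t-step
walker starting at each vertex ends up; two vertices in the same dense
region have similar rows. The vertex–vertex distance is the
degree-normalized L2 distance between rows,
r_ij = √Σ_k (Pᵗ_ik − Pᵗ_jk)²/d(k); community rows are the mean of member
rows (equivalently, the row of a walker starting at a uniformly chosen
member), and community distances use the same form. Agglomeration merges,
at each step, the *adjacent* pair of communities minimizing the Ward-style
cost Δσ = (1/n)·|C₁||C₂|/(|C₁|+|C₂|)·r²; this equals the increase in the
mean squared vertex-to-community distance, which the test suite verifies
against brute-force evaluation at every merge.

Assumptions worth stating: the network is undirected and connected (the
pipeline works on the largest connected component); weights are
nonnegative with strictly positive vertex degrees (guaranteed by the
weight floor); modules are non-overlapping by construction.

### Parameters

| parameter | default | meaning |
|---|---|---|
| t | 3 | walk length; short walks stay local, which is what makes the distances community-sensitive on sparse interactomes |
| max_size | 200 | community-size cap for partition selection; keeps modules small enough for functional interpretation |
| α | 0.01 | BH-FDR threshold below which a gene's activity is kept; filtered genes stay in the graph with activity 0 (`--raw-p` switches to unadjusted p) |
| ε (weight floor) | 10⁻⁶ | lower bound on edge weight; keeps the walk defined on expression-silent regions without measurably influencing it |
| B | 5000 | permutations per module size for activity and enrichment nulls (reduced in simulation studies; see problem sizes below) |
| self_loop_weight | 0 | optional lazy-walk self-loop; with t = 3 and the ε floor no laziness is needed, but 1.0 reproduces the convention of the igraph reference implementation and is used when cross-checking against it |

### Stopping criteria and the two modularity tracks

The merge history records modularity Q = Σ_C (e_C − a_C²) after every
step on two tracks: the walk's edge weights and the bare topology (each
edge counting 1). Partition selection takes the step, within the size
cap, that maximizes modularity on the **topology** track by default, with
`modularity_on="walk_weights"` available. The reasoning: the expression
signal already steers the *order* of merges through the weighted walk;
judging partition quality on the same weights makes the criterion nearly
blind to expression-silent regions (their edges carry only the ε floor,
so merging or splitting them barely moves weighted Q) and rewards
absorbing background genes adjacent to active genes, whose shared edges
carry half the signal's weight. Topological modularity keeps the
community criterion about interaction structure; in the synthetic
recovery study below this separation of roles recovers planted signal
modules more reliably. The weighted track remains available because an
all-weighted run reproduces the characteristically sparse partitions
(many singletons, few concentrated modules) of expression-dominated
analyses.

An alternative stopping criterion selects the step maximizing the best
permutation module score of the partition (`criterion="score"`). The
size cap, maximum modularity and maximum score are exposed as separate
selectors rather than combined into one rule, since no principled
arbitration between them exists; the cap always applies.

Determinism: ties in Δσ break toward the smaller (id, id) community
pair, ties in the selection objective toward the earlier step, so every
run is exactly reproducible.

### Module scoring

A module's cumulative activity is (mean member |FC|)², computed over
*pre-filter* activities so that module members and the null pool are
measured on the same scale. The null for size n is B draws of n genes
without replacement from the activities of all network genes (the pool
choice is configurable; with-replacement sampling is a flag). The score
standardizes the observed statistic against the null; the empirical
p-value uses the add-one estimator (1 + #{null ≥ obs})/(B + 1), so it is
never exactly zero. Only communities of more than three genes are
scored, one cached null per distinct size.

The squared-mean statistic is right-skewed at small n (draws from a
half-normal activity pool give P(|z| ≥ 3) ≈ 1.2% at n = 8 rather than
the Gaussian 0.3%), which is why the empirical p, not the z-score, is
the inferential quantity; the score is kept for ranking and reporting.

### Label enrichment

Enrichment of known labels (e.g. curated cancer genes) in a module of
size n is assessed against B random draws of n genes from the network
universe, one-sided (enrichment only; depletion is reported, not
tested). The exact hypergeometric tail is used as an internal
cross-check oracle — the test suite requires the sampling null's tail
frequencies to match it within Monte-Carlo error — but reported numbers
always come from resampling, which is the procedure being modeled. Both
the standardized count and the empirical p are reported, since either
may be wanted as "the" enrichment score. Genes absent from the label
list count as unlabeled.

## Synthetic studies: what they emulate and what they do not

The generator produces a planted-partition (stochastic-block)
interactome — communities of fixed sizes, within/between edge
probabilities p_in/p_out, resampled until connected — plus a probe-level
expression table in which genes of designated signal communities draw
fc ~ ±(effect + N(0, σ)) against a N(0, σ) background, with p-values
taken as the two-sided normal tail of fc/σ so that BH filtering
interacts with effect size the way it would for a real test statistic,
and a label list sampled Bernoulli per stratum. Default study
conditions: six communities of 25 genes, p_in = 0.3, p_out = 0.02, two
signal communities, effect = 3σ with σ = 0.5, label rates 0.8 (signal)
vs 0.1 (background).

Real interactomes are not stochastic block models: they are scale-free,
locally clustered, and their annotation is biased toward well-studied
genes; microarray fold changes are correlated across genes rather than
independent. Passing the synthetic recovery tests therefore shows the
machinery is correct and well calibrated under clean, identifiable
conditions — it does not certify recovery rates on real data, where
module boundaries are genuinely ambiguous.

## Numerical choices

- Pᵗ rows are kept dense; the implementation targets networks up to a
  few thousand vertices, where dense rows are faster and simpler than
  sparse maintenance. Row sums are preserved to < 10⁻⁹ at every step.
- Post-merge distances are recomputed exactly from stored probability
  rows (the Lance–Williams shortcut is algebraically exact too, but the
  direct recomputation is correct by construction and the σ-difference
  test pins it down). This differs from the igraph reference, which
  propagates approximate values for neighbors adjacent to only one merge
  parent; on 100 planted-partition graphs the two engines' max-Q
  partitions still agree in ≈ 98 cases, with residual differences
  attributable to that approximation, not to tie states.
- Degenerate cases: a zero-spread null flags the module rather than
  dividing by zero; an empty candidate set under the size cap returns
  the all-singleton partition with a warning; probe rows without a fold
  change are skipped and counted.
- Graph statistics follow the standard conventions (unnormalized
  betweenness, reciprocal-farness closeness, transitivity for the global
  clustering coefficient), recorded in the output metadata because
  verbal definitions of these quantities vary across tools. On large
  graphs, path statistics can be estimated from a stated number of
  sampled BFS sources (the diameter estimate is then a lower bound) and
  are flagged as estimates.

## Problem sizes in the validation suite

Simulation studies in the tests and the acceptance script use 100–150
gene networks, B = 500–2000 permutations, 20-seed replications, and 100
random graphs per fidelity sweep — sizes chosen so the full validation
runs in minutes while leaving the statistical margins (binomial noise on
recovery counts, Monte-Carlo error on tails) explicit in each check.

## Known limitations

- Overlapping modules are out of scope; each gene belongs to exactly one
  community.
- Identifier handling is uppercase symbol matching only — no alias or
  cross-species mapping; inputs are expected to be pre-mapped to HGNC
  symbols.
- Differential expression is consumed, not computed: the pipeline starts
  from a probe- or gene-level statistics table.
- The three stopping criteria are alternatives, not a combined rule; on
  data where they disagree materially, the choice is the analyst's and
  both modularity tracks plus the score selector are exposed for that
  comparison.
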