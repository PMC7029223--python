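# Methods

## Model and assumptions

`signedclust` operates on undirected graphs with finite, nonzero, signed
edge weights. The working assumption is that the sign of an association is
more trustworthy than its magnitude, and that cluster structure expresses
itself through *indirect* effects: the effect of node *u* on node *w* along
a path is the product of the edge weights, so an even number of negative
edges between two nodes is evidence they belong together. Directed graphs
are not supported — collapsing is attempted at read time, and reciprocal
edges with unequal weights are an error rather than an average, because
averaging could silently flip a sign.

### Scoring-matrix diffusion

The diffusion starts from the weighted adjacency matrix (zero diagonal — a
simple graph has no self-loops; self-loops in input files are dropped with
a warning) and repeats: square, normalize by the maximum absolute entry,
apply `x → x + 1/x` elementwise to nonzero entries, normalize again. The
inflation looks counterintuitive — it *shrinks* the relative gap between
small and large entries — but combined with squaring it drives every
nonzero entry toward ±1 while never flipping a sign on balanced graphs.

Numerical choices:

- **Convergence error.** The per-iteration error is the mean of *absolute*
  entry changes over nonzero entries; a signed accumulation would cancel
  oscillating terms and report spurious convergence. Iteration stops when
  100·E ≤ ε (ε is in percent).
- **Zeros.** The inflation is undefined at 0, so it is applied only to
  nonzero entries; squaring fills structural zeros in later rounds. Entries
  whose magnitude decays below 1e−12 are snapped to zero between rounds —
  during flip-flop iterations most entries decay toward denormals, where
  the reciprocal would overflow.
- **Degenerate state.** An all-zero (or non-finite) matrix at any
  normalization raises an error rather than propagating NaNs; this is the
  signature of unsuitable input (e.g. a directed graph forced through).

### Structural balance

Whether the diffusion converges is decided analytically, not empirically:
a signed graph is balanced iff every cycle has a positive sign product,
equivalently iff its nodes two-color so that negative edges cross colors
and positive edges do not. The test is a BFS two-coloring per connected
component, O(V+E) and deterministic; on failure it returns a witness cycle
with negative sign product (the conflicting non-tree edge closed through
the BFS tree). Routing on the analytic test avoids burning iterations to
*observe* a flip-flop.

### Unbalanced graphs: subset consensus

For unbalanced graphs, K edge subsets of size ⌈F·|E|⌉ are drawn uniformly
without replacement (independently across subsets, a single integer seed
governing all draws; subsets keep the full node set so matrices stay
index-aligned, isolated nodes contributing zero rows). Per subset: balanced
connected components are diffused to convergence and embedded at their
nodes' rows/columns (zeros elsewhere); the whole subset matrix receives
exactly one diffusion round — more would start flip-flopping; the two are
summed and normalized. An entry enters the consensus sum only when at
least a fraction R of subsets agree on its sign (at-least rather than
strictly-more-than, so that R = 1 means unanimity and K = 1 is vacuous);
the sum is then normalized. Subsets whose matrix degenerates are discarded
with a warning and K is effectively reduced.

### Oscillators and weak assignments

During flip-flop iterations the matrix limits ±1 are reached by only a few
entries, and the two alternating configurations split them: a node's
diagonal maximum and its row minimum are generally attained at different
iterations. Oscillator detection therefore runs the flip-flop loop for the
full iteration budget *tracking running extremes*, and declares node *v*
an oscillator when its diagonal reached ≥ 1 − tol and some row entry
reached ≤ −(1 − tol), with tol = 0.01 (no tolerance is prescribed by the
underlying theory; 1% of the limit is comfortably outside the near-zero
oscillation band). Balanced graphs have no oscillators by construction and
return an empty set with a warning.

The mean edge product P(v, t) averages, over **all** fewest-hop paths from
*v* to oscillator *t*, the product of edge weights scaled by the graph's
maximum absolute weight (the same normalization as the diffusion's; "how
to scale" is otherwise an open choice). Hop-count shortest paths are used
rather than weight-optimal paths — weights here are association strengths,
not costs. A disconnected pair contributes P = 0 with a warning: no path
evidence either way. Node *v* is weakly assigned if, for any oscillator in
its own cluster, (i) P ≤ 0 (the evidence contradicts the shared label) or
(ii) |P| < edgescale (the evidence is too thin; the absolute value makes
criterion (ii) purely about evidence strength, signs being criterion (i)'s
job). When several oscillators share the cluster, any single trigger
flags the node (conservative). Evaluating criterion (ii) against
oscillators *outside* the node's cluster is available as an off-by-default
switch (`all_oscillators`); which oscillators should count in that case is
genuinely underdetermined. Weak flags annotate nodes; membership is never
removed.

### Clustering and cluster-number selection

Rows of the scoring matrix are observations; Ward's minimum-variance
linkage on Euclidean distances is cut at every k in
[min_clusters, max_clusters] and the assignment with the maximal sparsity
score wins, ties toward smaller k. Cluster ids are renumbered by
decreasing size, then lexicographically smallest member, so output is
stable across runs. Clusters smaller than minsize·|V| are dissolved: the
retained submatrix is re-clustered with the same k-selection, and each
removed node joins the retained cluster maximizing the mean edge-weight
product over all fewest-hop paths to each member (averaging over all
shortest paths mirrors the mean-edge-product convention; raw weights are
used since a positive rescaling cannot change the argmax within a fixed
path length but paths of different lengths are not compared across
clusters anyway). If *every* cluster falls below the threshold the
original assignment is kept with a warning.

### Robustness

Replicate networks are produced by double-edge swaps — (u,v), (x,y) →
(u,x), (v,y) — rejected when they would create a self-loop or multi-edge.
Each weight travels with the endpoint that keeps it, so the degree
sequence is exactly preserved and the global weight (hence sign)
distribution is preserved, though not the weight-per-pair assignment. The
swap budget is ⌊fraction·|E|/2⌋ (each swap repositions two edges); if it
cannot be met within 200 attempts per swap the achieved fraction is
logged. Each replicate is re-clustered by the full pipeline; cluster-wise
stability is the maximum Jaccard similarity of each original cluster
against the replicate's clusters (original → replicate direction only),
node-wise stability the Jaccard similarity of the node's co-member sets
(weak nodes included by default; `exclude_weak` removes them first).
Intervals are percentile intervals (default 95%) over 100 replicates —
plain percentiles rather than a parametric form, as Jaccard values pile up
at 1.

## Synthetic benchmark

### What the gLV generator emulates

Each dataset simulates `n_species` = 100 taxa under generalized
Lotka–Volterra dynamics dx/dt = x∘(b + A·x) in `n_conditions` = 2
environments. A has off-diagonal entries nonzero with probability
`connectivity` = 0.05, drawn U(−0.5, 0.5), and diagonal −1
(self-limitation). Growth rates combine a base rate U(0.5, 1) with three
environmental factors: per-species susceptibilities ~ N(1, 1) and
per-condition factor strengths |N(3, 1)|, one factor positive and the
others negative, the positive one rotating across conditions so each
condition's cumulative effect is unique. Each of the 50 samples per
condition is an independent trajectory from x₀ ~ U(0.1, 1.1), integrated
by explicit Euler (dt = 0.01, T = 25) with multiplicative log-normal
environmental noise of standard deviation 0.5·√dt per step, and read out
at the end, when the dynamics are quasi-stationary. Without the noise
term every trajectory collapses onto the same attractor, all samples
within a condition coincide, and the inferred correlation network is a
complete graph — an uninformative regime no real dataset resembles.
Interaction matrices that cause population explosions (any abundance
exceeding 10⁶× the initial community total, or a non-finite value) are
regenerated, with a budget of 100 attempts. Ground-truth labels come from
seeded K-means (k = number of conditions, 10 restarts) on the species
profiles, since the environmentally induced grouping — not the interaction
matrix — is what the clustering is supposed to recover.

The resulting Pearson networks (α = 0.05, unadjusted, as a per-edge test)
are dense in edges but carry a periphery of low-abundance, noise-dominated
taxa attached by one or two significant correlations; the median
approximated node connectivity of the largest component is 1, versus ~50
and more for the bicluster networks below — the two topology regimes the
benchmark is meant to span.

### What the bicluster generator emulates

Ecosystems without biotic interactions, where co-occurrence is pure niche
filtering: no interaction matrix exists, and structure is planted directly
as rank-one blocks in a N(0, 1) noise matrix. Each block is an outer
product of positive feature loadings (signal·|N(1, ⅓)|, default signal 3)
and sample activations (N(2, 1) on the block's sample range). Default
blocks tile the entire feature set and split the samples evenly, so block
features correlate positively within and negatively across blocks, giving
two near-cliques joined by negative edges. The matrix is shifted by its
global minimum to satisfy nonnegativity — an affine map that provably
leaves every correlation unchanged (an exponential map was rejected: it
destroys the cross-block anti-correlations). Truth labels are block ids;
features outside every block (only possible with user-supplied positions)
are background.

### Noise injectors

- `permute_fraction`: ⌈fraction·cells⌉ entries selected without
  replacement, their values permuted among themselves; global by default
  (the scope of the permutation is underdetermined; per-row and per-column
  variants are provided as a switch).
- `add_multinomial_noise`: per sample, counts drawn from a multinomial
  with total = column sum × scale (default 1000) and probabilities
  proportional to abundances — sequencing-depth noise on scaled counts.
- `shift_weights`: w → (w+1)/2, mapping correlations from [−1, 1] to
  [0, 1]; an exact weight of −1 maps to 0 and the edge is dropped with a
  warning, since zero-weight edges are excluded by the graph invariant.

### Evaluation metrics

From the truth × prediction contingency table T (weak nodes excluded as
unassigned): Sn = Σᵢ maxⱼ tᵢⱼ / Σᵢ nᵢ with nᵢ the *full* truth-cluster
sizes (so unassigned nodes cost sensitivity), PPV = Σⱼ maxᵢ tᵢⱼ / Σⱼ mⱼ
with mⱼ the table's column sums, Acc = √(Sn·PPV), and separation
Sep = √(Sep_co·Sep_cl) where sepᵢⱼ = tᵢⱼ²/(rowᵢ·colⱼ) and Sep_co/Sep_cl
average the row/column sums of sep — the product of the fraction of
assigned nodes in the true cluster and of true nodes in the assigned
cluster, which penalizes overlap and cluster mixing. Assignments are
flagged pathological when one cluster exceeds 80% of the nodes or more
than 50 clusters appear (strictly-greater in both cases).

## Defaults

| parameter | default | meaning |
|---|---|---|
| ε (`epsilon`) | 2 (percent) | convergence threshold on 100× mean abs change |
| I (`max_iterations`) | 100 | diffusion cap, also the flip-flop budget |
| K (`n_subsets`) | 100 | subsets for the unbalanced consensus |
| F (`subset_fraction`) | 0.8 | edges per subset |
| R (`ratio`) | 0.8 | sign-agreement fraction for the consensus |
| `min_clusters`..`max_clusters` | 2..4 | sparsity search range (the method favors few clusters) |
| `minsize` | 0.1 | small-cluster threshold, fraction of nodes |
| `edgescale` | 0.8 | weak-evidence threshold on \|P\| (0.3 is the documented alternative for raw correlation weights) |
| rewire fraction | 0.1 | share of edges repositioned per replicate |
| replicates / CI | 100 / 95% | robustness resampling |

The search range 2..4 reflects that the sparsity criterion rewards coarse
splits; users expecting many clusters should raise `max_clusters`.

## What passing tests do and do not show

The generators provide ground truth and span two topology extremes
(sparse-interaction gLV vs dense niche-driven biclusters), but they do not
model compositionality, sequencing depth variation beyond the multinomial
injector, temporal autocorrelation, or inference-tool-specific edge
biases. Exact planted-bipartition recovery holds on clean balanced
two-block graphs; on noisy unbalanced networks the pipeline recovers the
main environmental split with separation around 0.6, not perfectly. A
known limitation: on networks with few or no negative edges the sparsity
score cannot reach 1 for any multi-cluster assignment and the clustering
mostly separates central from peripheral nodes; the pipeline warns in that
case.

## Degenerate inputs and tie-breaks

Edgeless graphs: sparsity undefined (error), diffusion degenerate (error).
Duplicate edges with equal weights merge silently; unequal weights are a
data error naming the pair. Zero-weight edges are dropped with a warning
at read time. Ties in cluster-number selection go to smaller k; ties in
small-cluster reattachment go to the smaller cluster id; Jaccard of two
empty co-member sets is 1.
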