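# Methods

## Model and procedure

The selector treats signature construction as greedy forward selection with
two orthogonal criteria. Statistical value is the marginal change of the
soft-margin linear-SVM dual objective: after solving the dual on the
selected set S, the multipliers α are frozen and appending candidate m
changes the kernel by the rank-one term x_im·x_jm, giving
ΔJ(m) = −½(Σ_i α_i y_i x_im)². Biological redundancy is the total influence
factor: on an undirected interaction graph, a pair of genes at shortest hop
distance d carries influence base^(1−d) (base 2 by default), and a
candidate's TIF is the sum of its pairwise influences against the selected
set. Each iteration shortlists the top-t candidates by |ΔJ| and admits the
TIF minimiser; the SVM is refit on the enlarged set before the next
iteration (the only reading under which the next iteration's α are
defined). The first feature is chosen by maximum mutual information with
the label (equal-width 10-bin plug-in estimate, natural log) or,
alternatively, by marginal power against the empty set.

Features that cannot be mapped to a graph gene are "unresolved". Their
interaction structure is modelled by a single probability p: a mapped
candidate scores p·|Q| + Σ_{s∈R} base^(1−d) over the unresolved (Q) and
resolved (R) parts of the selected set; an unmapped candidate scores p·|S|.
p is estimated from the incomplete graph itself: retain a fraction s of the
edges, compute the average number of other vertices reachable per vertex,
fit the saturating geometric form f(s) = A − B·q^s by nonlinear least
squares over s = 10%…100%, read the completed-graph reachability off the
asymptote A (or f at a chosen s > 100%), and divide by the total gene count
(default 20,500 for human). An asymptote of 180 yields the default
p = 0.0088.

Single rankings on small-n expression data overfit, so the loop runs on K
stratified subsets each holding a fraction (default 0.8) of the training
samples, drawn without replacement. The K rankings are truncated to length
N and stacked into a K × N matrix; an appearance at 1-based column k earns
N − k, weights are summed over rows, and the N largest totals form the
final ranking.

## Parameters

| parameter | default | meaning |
|---|---|---|
| t | 10 | candidate-set size per iteration |
| K | 50 | subset count for rank aggregation |
| fraction | 0.8 | per-subset share of training samples |
| N | 150 | ranking length and position-weight scale |
| decay_base | 2 | per-hop influence attenuation |
| p | 0.0088 | expected unresolved-pair influence |
| no_path_influence | 0 | influence of disconnected mapped pairs |
| n_bins | 10 | mutual-information discretisation |
| regularization | 1.0 | SVM box constraint C |
| split_ratio | 0.8 | train share of the 4:1 train/test split |
| total_genes | 20500 | denominator of the p estimate |

A single master seed fans out to per-stage sub-seeds through spawned
`numpy.random.SeedSequence` streams, so the split, the subset draws and any
synthetic generation are independently reproducible.

## Design choices where the design was open

- **No-path convention.** Taking d = 0 for a disconnected pair would give
  influence base^1 = 2, *above* the direct-edge influence of 1 and against
  the premise that influence decays with distance. Disconnected (or
  unmappable-to-the-graph) resolved pairs therefore contribute
  `no_path_influence`, default 0. The value is configurable.
- **Same-gene pairs.** Two features mapping to one gene are treated as
  distance 0, influence base (= 2), the supremum of the decay: maximal
  redundancy. The pairwise formula itself is undefined at i = j, so this
  only arises through many-to-one mappings.
- **Ranking sign.** Under frozen α, ΔJ ≤ 0 for every candidate, so a
  literal descending-ΔJ sort would favour the *least* useful feature.
  The default ranks by |ΔJ| (equivalently w_m²), which matches the
  stated intent — the capability of a feature to improve classification;
  `literal_delta_j_order` restores the literal sort, and
  `retrain_per_candidate` computes a two-sided ΔJ by refitting per
  candidate.
- **Edge direction and type.** Interactions are treated as undirected and
  untyped: influence as mutual redundancy is symmetric and only topology
  enters the metric. A directed mode is deliberately not offered.
- **Empty selected set.** The dual with an all-zero kernel maximises Σα_i
  under the box and balance constraints; the uniform within-class optimum
  α_i = C·min(n+,n−)/n_{y_i} is used in closed form, making the empty-set
  marginal power a squared class-mean contrast.
- **Curve family for reachability.** f(s) = A − B·q^s is the simplest
  convergent geometric family with a finite asymptote and three
  identifiable parameters from ten points; near-constant inputs short-cut
  to A = mean, B = 0. Fitting uses bounded nonlinear least squares
  (A, B > 0, 0 < q < 1).
- **Ties.** Candidate ranking ties break by matrix column order; TIF ties
  break by better ΔJ rank then column order; aggregation ties break by the
  earliest column at which a feature ever appears, then lexicographic id.
  All outputs are byte-deterministic under (config, seed).
- **Normalisation** of expression values before SVM training is exposed as
  a `standardize` flag, default off; imputation policy (`drop_feature` vs
  `mean_impute`) is likewise explicit, defaulting to dropping features
  with missing values so no modelling assumption is injected silently.

## Synthetic data: what it emulates and what it does not

The generator plants b blocks of correlated informative features in
balanced two-class Gaussian data: x = μ_class ± effect/2 + √ρ·z_block +
√(1−ρ)·ε, giving unit marginal variance, pairwise within-block correlation
ρ and an exact between-class mean gap of `effect_size`. Matching graphs
wire each block as a connected subgraph (spanning path plus
Bernoulli(p_within) clique edges) with Bernoulli(p_between) background
edges, and mark a uniform `unresolved_fraction` of features (default 0.6,
the regime where most candidates lack a mapping) as unmappable.

This captures exactly the structure the selector exploits — statistically
redundant features that are also graph-adjacent — and nothing else: no
probe-level artefacts, no heavy-tailed or batch-structured noise, no
correlation between blocks, and graph modules that coincide perfectly with
correlation blocks. Passing tests therefore demonstrate the algorithmic
behaviour (redundant blocks are spread over, unresolved features are
handled consistently, rankings are stable and deterministic), not
performance on any real platform.

The redundancy-suppression check runs 5 blocks × 4 features at ρ = 0.8,
effect 1.5 SD, n = 120 over 20 generator seeds, with 60 total features and
every feature mapped — blocks as disjoint cliques — and compares the
number of distinct blocks covered by the first five picks against a
graph-blind run. Problem sizes throughout the suite (tens of features,
≤ 200 samples, K ≤ 5 subsets in composition tests) keep every stage
exercised end to end at desk scale.

## Numerical notes and limitations

- The SVM is libsvm's SMO (scikit-learn `SVC`, linear kernel, tol 1e−6);
  the dual objective is re-evaluated from the returned α rather than
  trusting the solver's internal value. Fits are deterministic for fixed
  input.
- The fixed-α ΔJ is exactly −½w_m², so scoring all remaining features is a
  single matrix–vector product per iteration; the ensemble over K subsets
  is linear in K.
- Average reachability is computed from connected components
  (Σ|C|(|C|−1)/|V|), equivalent to per-vertex BFS counts but linear time.
- The plug-in MI estimator is upward-biased with many occupied bins; it is
  used only for the argmax seed choice, where the bias can matter when a
  noise-free and a noisy feature carry comparable signal — the
  marginal-power seed method avoids binning altogether.
- The p estimate extrapolates a parametric curve far beyond the observed
  range; the asymptote is identifiable but model-dependent, and alternative
  convergent families could give different completed-graph reachabilities.
- Genes in several pathways (fully-connected mode) join all of their
  cliques; no edge is added between genes sharing no pathway.
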