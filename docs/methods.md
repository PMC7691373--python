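# Methods

## The model

`pmil` predicts missing edges in a bipartite graph G(U, V, E) — drugs and
protein targets, users and items, people and events — by a three-stage
pipeline.

**1. Weighted one-mode projection.** The U-projection G_u joins two
U-nodes A, B iff they share at least one V-neighbour, with integer weight

    WP(A, B) = |Γ(A) ∩ Γ(B)|,

the shared-neighbour count. Simple (unweighted) projection destroys
topological information — two different bipartite graphs can have the same
simple projection — so the weight is retained. Every projected edge is
called a *pattern*: evidence that a U-pair already co-occurs through the
other side.

**2. Two scores per pattern.** Each pattern (and, in general, each
same-side node pair) gets:

*Potential energy*, a m·g·h analogue on the projected skeleton:

    PE(A, B) = (d_A d_B) · (Σ_{z ∈ Γ(A)∩Γ(B)} cl_z) · (1 / sd(A, B))

with d the degree, cl_z the clustering coefficient of a common neighbour,
and sd the shortest-path hop count. When the pair has no common neighbour
the clustering sum is replaced by the constant 0.1 so degrees and distance
still discriminate such pairs.

*Mutual-information score*, the negative conditional self-information of
the link event given the pair's common neighbours:

    S^MI_xy = Σ_{z ∈ O_xy} I(L¹; z) − I(L¹_xy)

where I(L¹; z) is the mean, over ordered neighbour pairs (m, n) of z, of
I(L¹_mn) − I(L¹_mn | z). The unconditional link information uses a
path-entropy estimate of the no-link probability,

    p(L⁰_mn) = C(T_l − d_m, d_n) / C(T_l, d_n),

with T_l the projected edge total, and the conditional term uses the
clustering coefficient of z as p(L¹_mn | z). Higher S^MI means a likelier
link; the score can be negative.

**3. PMIS ranking.** The total pattern weight is the raw sum

    W_t(A, B) = PE(A, B) + S^MI_AB + WP(A, B)

and the PMIS score of a cross-side candidate (A, i) is the sum of W_t over
all patterns covered by (A, i), i.e. over {A, C} with
C ∈ N_u(A) ∩ N(i). Candidates are ranked by descending PMIS.

### Assumptions

- The common neighbours in O_xy contribute independently (the additive
  form of the MI sum takes this as given).
- No degree correlation in the no-link probability estimate.
- The input graph is simple, undirected and unweighted; side membership
  is fixed by the edge-list columns.

## Numerical and structural choices

- **Skeleton convention.** Degrees, triangles, clustering coefficients and
  shortest distances are computed on the *unweighted* skeleton of the
  projection; WP enters only as the third additive term of W_t. The MI and
  PE formulas are stated for plain graphs, and this keeps the three terms
  interpretable.
- **Logarithm base.** All information quantities use base 2 (bits).
  Rankings are base-invariant; bits is the information-theoretic default.
- **Clamping.** Probabilities are clamped into [1e-10, 1] before every
  logarithm. Without this, a common neighbour with zero clustering
  coefficient or a structurally impossible link produces infinite
  information. The clamp keeps every score finite and preserves ordering;
  ε only shifts the (rare) clamped terms by a common ceiling
  (−log₂ 1e-10 ≈ 33.2 bits).
- **Degree-deficient nodes.** The clustering coefficient is defined as 0
  for degree < 2 (the standard convention; the defining ratio divides by
  d(d−1)). Common neighbours with fewer than two projected neighbours are
  skipped in the MI sum — the mean mutual information over their neighbour
  pairs is undefined.
- **Ordered vs unordered pairs.** The normaliser |Γ(z)|(|Γ(z)|−1) in
  I(L¹; z) counts ordered pairs; every summand is symmetric in (m, n), so
  the implementation iterates unordered pairs and doubles — the two
  readings coincide exactly. Documented so ports agree.
- **Disconnected and degenerate pairs.** sd = ∞ gives PE = 0 by default
  (the continuous limit of 1/sd), overridable via
  `PEParams.disconnected_value`. An endpoint of projected degree 0 gives
  PE = 0 through the degree product. A projection with no edges at all
  yields no patterns and every PMIS score 0.
- **Determinism.** Node order is first-seen everywhere; unordered pairs
  are canonicalised lexicographically; rank ties break by the canonical
  pair order; all randomness flows from explicit integer seeds. Two runs
  with the same input and seed produce byte-identical outputs.
- **Large graphs.** The binomial ratio in p(L⁰) is evaluated in log-gamma
  space, so projected edge totals in the tens of thousands do not
  overflow.
- **Which side to project.** Prediction runs on the projected side;
  the CLI's `--side auto` projects the smaller side, which is also the
  cheaper one (the pipeline is cubic in the projected side's size).
- **PE on cross-side pairs.** PE and S^MI are same-side quantities; the
  PMIS aggregation only ever consumes pattern weights, so no cross-side
  PE is computed.

## Baselines

CN, JC, PA and CS are included for harness parity. The classical indices
are unipartite; a cross-side pair never shares direct neighbours. They are
adapted through the pattern-covered geometry — the projected neighbourhood
N_u(a) is compared against the bipartite neighbourhood N(i), both subsets
of U — except PA, which uses plain bipartite degrees. This adaptation is
this package's convention, which is why external published baseline
numbers are not comparison targets.

## Evaluation protocol

K-fold edge holdout (default K = 10): edges are partitioned uniformly;
each fold in turn is the probe set E^p, the rest train the model.
Candidates are all U×V pairs absent from the training graph, so probe
links compete with genuinely nonexistent ones.

- **AUC (sampling form).** N^t random (probe, nonexistent) score
  comparisons; AUC = (N^h + 0.5 N^s)/N^t. Default N^t = 10,000 per fold,
  seedable. The estimator converges to the exact Mann–Whitney AUC as
  N^t → ∞ (property-tested at 10⁵ draws).
- **Precision.** Fraction of the top-L ranked candidates that are probe
  links; L defaults to the probe-set size. Precision@K at K ∈ {10, 20, 50}.
- **Prediction power.** log₁₀(precision / random precision) with random
  precision L/(|U||V| − (E − L)), E the training edge count; zero
  precision maps to −∞.
- **Averaging.** Reports are averaged arithmetically over folds × repeats;
  repeats use independently spawned seeds.

### Random-scorer calibration

The harness is checked against a random scorer, whose mean AUC must be
0.5. A *single* random scoring of a small candidate set has exact-AUC
standard deviation ≈ √((n₁+n₂+1)/(12 n₁ n₂)) — about 0.056 for ~30 probe
vs ~270 nonexistent links — so no number of comparison draws can pin one
scoring to 0.5 ± 0.02. The calibration therefore averages 100 independent
random scorings of 1,000 sampled comparisons each (10⁵ comparisons in
total), driving the standard error of the mean below 0.01.

## Synthetic data

The generator emulates the regimes of published bipartite benchmarks
(affiliation networks of a few dozen nodes up to drug–target networks
with thousands of nodes and average degrees from ~1.3 to ~41): side sizes,
exact edge count, and either a uniform edge distribution or a
preferential-attachment style growth (endpoint probability ∝ degree + 1)
producing right-skewed degrees. Isolated nodes are allowed by default —
very sparse real networks have them — and `min_degree_one` forces a
spanning assignment first. What it does *not* reproduce: community
structure, degree–degree correlations, bipartite clustering profiles, or
the noise processes of experimentally measured interaction data. Passing
recovery tests on these graphs shows the pipeline extracts planted
shared-neighbour signal; it does not certify accuracy on any real
dataset.

Test and acceptance problem sizes are deliberately small — graphs up to
20+20 nodes and 120 edges, 100 random graphs of ≤ 15+15 nodes for the
oracle-equivalence sweep — chosen so the entire suite re-runs in seconds
while still exercising every code path; the statistical checks were sized
to have large margins at those scales (e.g. the synthetic-recovery t-test
rejects AUC = 0.5 at p ≈ 3·10⁻⁷).

## Known limitations

- O(n³)-ish cost in the projected side's size when scoring all
  disconnected pairs; restrict `candidates` for large graphs.
- The three W_t terms live on different scales (WP ≥ 1 integer, PE small,
  S^MI in bits, possibly negative) and are summed raw by definition; no
  normalisation is applied, and the components are exposed in the output
  for transparency.
- Input edge weights, directed or multi-edges are unsupported.
- The MI independence assumption over common neighbours is heuristic;
  densely clustered neighbourhoods double-count evidence.
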