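# Methods

## The model

`cvxndl` learns a small dictionary of k × k interaction patterns from a
large undirected network.  The data stream is a sequence of *patches*:
adjacency submatrices induced by k-node path homomorphisms sampled from
the network, flattened to d = k² vectors.  Online matrix factorization
fits a dictionary **D** ∈ ℝ^{d×K} and per-sample nonnegative codes Λ by
minimizing, in expectation over the stream,

    ℓ(x, D) = min_{Λ ≥ 0} ‖x − DΛ‖² + λ‖Λ‖₁ .

After each sample the aggregated history

    A_t = (1 − w_t) A_{t−1} + w_t Λ_t Λ_tᵀ ,
    B_t = (1 − w_t) B_{t−1} + w_t Λ_t x_tᵀ ,      w_t = 1/t ,

defines the quadratic surrogate Tr(D A_t Dᵀ) − 2 Tr(D B_t), the standard
majorization used by online dictionary learning.

The distinguishing constraint is *convexity*: each element D[:, j] must be
a convex combination of its **representative set** — a capacity-bounded
collection of real patches that were actually emitted by the sampler:

    D[:, j] = Σᵢ w_{j,i} X̂(j)[:, i],   Σᵢ w_{j,i} = 1,  w_{j,i} ≥ 0 .

Every element is therefore an overlay of observed subnetworks and can be
mapped back to the genomic (or generic node) coordinates of its
representatives, which is what makes the output interpretable for
multiway chromatin contact data: an element *is* a weighted bundle of real
multiway interactions, not an abstract factor.

## Sampling

For hypergraph inputs (multiway contacts over genomic bins), fragments are
binned by midpoint into fixed 500-base bins, hyperedges are clique-expanded
into an ordinary graph, and the graph is restricted to its largest
connected component.

Patches are sampled by a pivot Markov chain over path homomorphisms
(ordered k-tuples in which consecutive nodes are adjacent; tuples need not
be injective and walks may backtrack).  One transition: propose v uniform
from the neighborhood of the pivot x[1]; accept with

    β = min{ (W_{k−1}(v) / W_{k−1}(u)) · (deg u / deg v), 1 } ,

where W_{k−1}(u) counts length-(k−1) walks from u (computed by k−1 sparse
mat-vec products, never a dense matrix power); then regrow the tail as a
directed uniform random walk.  Detailed balance gives the pivot marginal
π(u) ∝ W_{k−1}(u); on regular graphs β ≡ 1.  The chain is initialized by
rejection sampling and run with a 1,000-step burn-in and no thinning —
the online learner tolerates correlated samples, and the exact stationary
law over homomorphisms (pivot marginal × walk probability) is available in
closed form for small graphs and is used as the test oracle.

Sampling is pre-generated into a pool before optimization.  The
initialization subset (default 500 patches) is drawn *at random* from the
pool rather than taken from its head: the chain mixes slowly between
well-separated regions, so the head of the stream can be structurally
unbalanced.

## The online update

Per observed patch:

1. **Code** against the current dictionary (nonnegative lasso; NNLS when
   λ = 0).
2. **Assign** the sample to the nearest element (Euclidean; ties to the
   lowest index).
3. **Aggregate** A_t, B_t with w_t = 1/t.
4. **Update the representative set** of the assigned element j: append the
   sample; while over capacity, score every removal candidate by re-solving
   the simplex weights on the remaining set and evaluating the surrogate
   restricted to column j, and keep the removal with the smallest
   objective.  Removing the newcomer is always a candidate, so the
   column-restricted objective never increases; ties favor removing the
   newcomer (set unchanged).  Representative sets inherited from
   initialization can exceed the capacity N_max; on their first update they
   are bulk-trimmed by one full weight solve (keeping the N_max
   largest-weight members plus the newcomer) before the per-sample search.

The simplex-constrained column subproblem min_{w ∈ Δ} a wᵀGw + 2cᵀw
(G = X̂ᵀX̂, a = A_t[j,j]) is solved by accelerated projected gradient
(FISTA with gradient-based adaptive restart) at the 1/L step, terminating
on a KKT residual ≤ 1e−6 relative to the problem scale, with a 10⁴
iteration cap and warm starts from the incumbent weights.  Plain projected
gradient met the same contract but needed an order of magnitude more
iterations on the near-singular Gram matrices that collinear binary
patches produce.  When a = 0 (an element with no recorded usage) the
objective is linear and the vertex rule applies.

Convergence of the fit is declared when the mean surrogate loss over a
500-step window changes by less than `tol` (default 1e−4, relative)
between consecutive windows; hitting `max_iters` (default 10⁶) without
convergence is reported on the results object and logged, never silently
accepted.

### Baseline

`OnlineNDL` shares the sampling, coding and history aggregation but
replaces the convex-hull constraint with the classic block-coordinate
surrogate step, D[:, j] ← clip(D[:, j] + (B[j,:]ᵀ − D A[:, j]) / A[j, j],
0, 1).  Its elements are not convex combinations of real patches — it is
the accuracy reference, not the interpretable method.

## Reconstruction and scoring

To score a dictionary, patches are sampled from the target network with
the same pivot chain, coded against D, and the clipped approximations
DΛ ∈ [0, 1] are accumulated onto the node pairs of each patch (ordered
pairs, diagonal ignored) together with visit counts; W = sum / count on
visited pairs.  Ranking visited (unordered) pairs by W against the true
adjacency yields the average precision (threshold-averaged, ties grouped —
`sklearn.metrics.average_precision_score`); unvisited pairs are excluded.
A random-dictionary baseline (uniform convex combinations of randomly
drawn pool patches) provides the floor reference.

Coverage matters for this comparison: with many patches per pair, the
position structure of path sampling alone separates edges from non-edges
(consecutive patch positions are always true edges), and every
dictionary — random included — approaches the ceiling.  The ordering
between learned and random codebooks is therefore assessed at low visit
coverage (one or two visits per pair), where each pair's score comes
from few approximations and per-patch fidelity decides the ranking.

## Per-element summaries

* **Importance score** γ(i) = A_t[i,i]² / Σⱼ A_t[j,j]² — normalized
  squared usage; sums to 1.
* **Density** ρ = mean of the k² element entries — interaction richness.
* **Median adjacent distance** d_med — median genomic distance between
  bin midpoints of consecutive nodes over all representative tuples of an
  element (pairs on different chromosomes are skipped); requires the bin
  table, reported in bases.

## Synthetic benchmarks and what they do (not) show

The stochastic block model benchmark (defaults: 3 blocks × 100 nodes,
p_in = 0.3, p_out = 0.02) emulates the sparse, community-structured,
path-dominated networks that clique-expanded multiway contact data
produce.  Desk-scale learner settings for this benchmark are k = 8,
K = 9, 500 initialization + 5,000 online samples and 5,000 reconstruction
patches, scaled down from the full-data setting (k = 21, K = 25, 20,000
samples) to keep a complete three-seed run within minutes on one CPU; all
are overridable.  Passing it shows the full pipeline — sampling, convex
online learning, reconstruction — preserves network structure at high
average precision.  It does not emulate read-level assay noise, droplet
barcoding artifacts, restriction-fragment geometry or hyperedge-size
distributions of real multiway contact data, and chromosome-scale
accuracy claims require the real data.

The parameter-recovery benchmark plants three structurally distinct,
degree-matched 8-regular motif types as disjoint copies joined by sparse
linkers: complete bipartite K₈,₈, the clique K₉, and a girth-6 sparse
bipartite graph built from a Sidon difference set.  Degree matching
matters because the pivot chain's stationary mass scales like
degree^(k−1): unmatched motifs are effectively never sampled.  The
recovery targets are the motifs' *patch signatures* — the patch a
self-avoiding k-walk induces: the parity checkerboard, the complete
patch, and the bare path.  These, not Monte-Carlo expected patches, are
the right ground truth: sampled patches carry revisit artifacts
(backtracking walks), and the factorization actively denoises them —
with near-one-hot coding (harness λ = 5) each element's surrogate target
is the usage-weighted patch mean whose saturation at the convex-hull
faces lands on the pure signature.  A K = 3 learner recovers all three
signatures to within 0.1 per entry after greedy matching.

## Numerical choices and degenerate inputs

* Codes are constrained nonnegative (the method is NMF-style; keeps
  elements additive-parts interpretable).  λ defaults to 1.0 and is the
  main sensitivity: much larger values push coding toward one-hot
  (cluster-mean-like elements), λ = 0 gives plain NNLS coding.
* Convexity invariants are enforced to tight tolerances (reconstruction
  residual ≤ 1e−8, simplex sum ≤ 1e−10) and checked by
  `Dictionary.validate()`.
* Ties: nearest-element assignment → lowest index; removal search →
  newcomer, then lowest index; half-open bins put boundary midpoints in
  the upper bin.
* Disconnected inputs are restricted to the largest component (share of
  dropped nodes logged); empty hypergraphs, empty streams, undersized
  pools and non-finite samples raise immediately.
* All randomness flows from one `numpy.random.Generator` per run; seeds
  are recorded in archives and reports.

## Known limitations

* The acceptance probability β is derived for the k-path template;
  generic motifs are supported only by enumeration and rejection sampling
  on small graphs (test oracles).
* Batch coding (N > 1 samples per step) is not implemented.
* Reconstruction accumulates dense n × n score/count arrays up to
  n = 5,000 nodes and switches to hashed pair accumulation beyond; very
  large networks will want a blocked implementation.
* The w_t = 1/t weight schedule is fixed by default; alternative schedules
  are accepted by the history update but untested at scale.
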