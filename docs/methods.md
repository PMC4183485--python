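# Methods

## Data model

A `Network` is an undirected simple graph with opaque, case-sensitive string
node labels. Self-loop input lines are dropped with a warning; duplicate
edges and both orientations collapse silently. Edge weights (the optional
third `.abc` column) are parsed and stored but never consulted by the
clustering engines or the cartography — every algorithm works on the
unweighted adjacency matrix; the weighted view exists only for export.
Node order is insertion order, so all matrix views are reproducible.

A `Partition` is a total map node → module label; module labels are opaque
strings, with contiguous internal indices assigned in first-seen order.

## Clustering engines

**Spectral (random-walk framework).** Unnormalized mode uses L = D − A;
normalized mode the random-walk Laplacian L = I − D⁻¹A, with the row of a
degree-0 node replaced by the identity row (such a node behaves as its own
connected component). Eigenpairs are obtained through the symmetric form
I − D^{−1/2} A D^{−1/2} and mapped back, which keeps the computation real
and stable; the k eigenvectors of the smallest eigenvalues form the
embedding U, with each eigenvector's sign fixed so its first nonzero entry
is positive (restart-reproducibility). Rows of U are clustered by Euclidean
k-means. The symmetric-normalized variant is deliberately not offered; the
random-walk form is the one the cited framework defines.

**k-means on graphs.** Node i is embedded as row i of a node×node distance
matrix — shortest-path hop counts (unreachable pairs get the finite
surrogate n, strictly larger than any path, keeping the embedding defined
on disconnected graphs) or Hamming distance between adjacency rows over all
n coordinates — and clustered with standard Euclidean SSE k-means; the SSE
objective and centroid-as-mean update require a vector space, which is why
the embedding, rather than a medoid variant, is used. Lloyd iterations with
k-means++ initialisation, default 10 restarts keeping the best SSE; an
empty cluster is reseeded with the point currently farthest from its
centroid. Restarts alternate k-means++ with uniform distinct-point seeding:
the two schemes populate different basins, which measurably improves global
optimality on small instances (verified against exhaustive enumeration of
all kⁿ assignments for n ≤ 8). The SSE(k) scan reports the curve only;
choosing the elbow is explicitly left to the user, and no automatic elbow
detector is implemented.

**MCL.** The transition matrix starts from adjacency plus unit self-loops
(standard stabilisation against period-2 oscillation), column-normalised.
Each iteration squares the matrix (expansion), raises entries elementwise
to the inflation power r (default 2.0), zeroes entries below 1e-10 and
renormalises columns; a column emptied by pruning is parked on its own
diagonal. Iteration stops when the max elementwise change drops below 1e-6
(default cap 200 iterations; non-convergence returns the current partition
with a Python warning). Clusters are the connected components of the
symmetrised nonzero structure of the limit matrix — with this reading every
node lands in exactly one cluster, so no separate attractor tie-break is
needed. Inflation r ≤ 1 is rejected.

## Cartography

κ_i counts a node's neighbours in its own module; Σ_s κ_is = k_i by
construction. The z-score uses the population standard deviation, with
σ = 0 → z = 0 by convention; the default standardisation is per-module,
and a `global` mode (mean/σ over all nodes' κ) is provided for sensitivity
analysis, since both readings of "the overall degree distribution" occur in
the literature this follows.

The modified participation coefficient is the single-term form
P = 1 − (κ_own/k)². It is the natural fix for the original definition's
1 − 1/N ceiling: it ignores how the external links distribute over the
other modules, depends only on the intra fraction, and attains 1. The
original two-descriptor definition remains available (`variant="original"`)
and is used in tests as the bound P_original ≤ P_modified.

Region boundaries: upper P boundaries belong to the lower region; z at the
hub cut is a hub. The default R3/R4 cut is stored as the expression
1 − 0.35² rather than the decimal 0.8775, so that a P computed as
1 − (κ/k)² with κ/k = 0.35 lands exactly on the boundary under identical
floating-point arithmetic — the "fewer than 35% intra links" reading of R4
is then exact, not approximate. The remaining defaults (0.05, 0.62; hub
0.30, 0.75; z_hub 2.5) follow the classical cartography. Isolated nodes get
k = κ = 0, P = 0, z = 0, hence R1.

## Builders

Contact networks use a closed distance interval [d_min, d_max] (default
[4, 8] Å): "within" is read inclusively and both ends are configurable. No
sequence-separation filter is applied — the 4 Å lower bound already excludes
covalently bonded neighbours (Cα–Cα ≈ 3.8 Å), which is the point of the
window. Co-expression uses Pearson correlation on pairwise-complete
samples (missing values are never imputed as zeros); pairs with fewer than
3 complete samples are skipped with a warning, and zero-variance profiles
produce no edges. The threshold comparison is strict (>).

The Erdős–Rényi generator is G(n, m) — exactly m distinct edges sampled
uniformly without replacement — not G(n, p), because the reference
architectures it reproduces are specified by node *and* edge counts. The
Barabási–Albert generator seeds with a clique on m_attach+1 nodes and
attaches each new node to m_attach distinct targets with probability
proportional to current degree, giving the closed-form edge count
C(m_attach+1, 2) + (n − m_attach − 1)·m_attach. The planted-partition
generator (independent Bernoulli edges, p_in within and p_out between
modules) supplies ground truth for recovery experiments.

## What the synthetic data does and does not show

Recovery and invariant tests run on planted-partition graphs (e.g. 4
modules × 25 nodes, p_in = 0.5, p_out = 0.02), small Bernoulli random
graphs with random partitions, and hand-built fixtures (cliques, stars,
bridges). These exercise the algebra and the algorithms under controlled
modularity; they do not emulate the degree heterogeneity, weight structure
or noise of real contact maps and co-expression data. Passing them shows
the machinery is correct, not that a particular biological network will
yield a clean partition — there, the cluster count k remains a user
judgement (via the SSE scan or prior knowledge). Problem sizes in the test
suite (≤ 1000-node random graphs, 100-node ensembles, 200 exhaustive
k-means instances with n ≤ 8) were chosen as the smallest that make each
property non-trivial.

## Numerical choices

* Eigenvalue zero-multiplicity tests use |λ| < 1e-8; eigenvector sign fix
  threshold 1e-12.
* k-means SSE is recomputed against exact final-assignment means before
  reporting, so the returned SSE always matches its partition.
* MCL column-stochasticity is maintained to ~1e-9 after every inflation.
* Output tables print floats with 6 significant digits for diffability;
  every CLI output begins with a `# seed=<n>` header line, and identical
  argv + seed give byte-identical files.
* `classify_node` tolerates P within 1e-9 outside [0, 1] (float noise from
  1 − (κ/k)²) and errors beyond that.

## Known limitations

Directed graphs, multigraphs, weighted-graph clustering, overlapping
communities and modularity-maximisation methods are out of scope. The PDB
reader consumes only ATOM/CA records (first altLoc kept, HETATM excluded);
mmCIF is not supported. The CLI's attribute join expects a TSV keyed by
node label.
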