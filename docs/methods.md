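# Methods

## Tree encoding

A rooted binary tree on `n` labeled leaves is built left to right: start with
leaves 0 and 1 on pendant edges under the root; for `m = 2..n−1`, subdivide
the pendant edge labeled `v_m` and hang leaf `m` from the new vertex. The
vector `v` with `v_0 = v_1 = 0` and `0 ≤ v_m ≤ m−1` is the tree's *ordered*
encoding; construction and decoding are linear in `n`. At a fixed assignment
of integer labels to taxa (an *ordering* σ) the encoding reaches exactly
`(n−1)!` of the `(2n−3)!!` rooted topologies. A topology admits at least
`2^(n−1)` orderings (verified exhaustively for n ≤ 6 in the tests). Within
one ordering, suppressing the root maps ordered vectors onto unrooted
topologies exactly 2-to-1 (verified exhaustively for n ≤ 7); this is the
degeneracy that can leave the unrooted objective flat between two tied
rootings at convergence, and why the decoded tree is read off by row-wise
argmax (ties toward the smaller column).

## Discrete and relaxed objective

The BME length is implemented as the unordered-pair sum
`L = Σ_{i<j} D_ij 2^(−e_ij)`; the minimizer is unaffected by the alternative
ordered-pair convention, which only doubles the value. Path lengths `e_ij`
come either from a tree (LCA depths) or directly from a vector by replaying
the construction; *rooted* mode counts the root vertex on paths that cross
it (two leaves of a cherry are 2 edges apart), *unrooted* mode counts paths
after the root is suppressed (1 edge apart). An optional log-sum-exp
evaluation of `L` is available for distances spanning many orders of
magnitude and agrees with the direct sum to 1e−12.

The relaxation replaces the single vector by independent rows:
`W_mj = P(v_m = j)`, a row-stochastic lower-triangular matrix (rows 0 and 1
are fixed point masses). The expectation `E_ij = E[2^(−e_ij)]` obeys a
closed recursion over the leaf-insertion index `k`: inserting leaf `k` at
pendant edge `x` lengthens every path ending at `x` by one edge and creates
the new paths `e_xk = 2`, `e_ik = e_ix + 1`, so

```
E_ij ← E_ij · [1 − ½(W_ki + W_kj)]            (i < j < k)
E_ik ← ½ Σ_{x<k, x≠i} E_ix W_kx + ¼ W_ki      (i < k)
```

initialized with `E_01 = ¼` (rooted) or `½` (unrooted). The objective is
`F(W) = Σ_{i<j} D_ij E_ij`, computed in `O(n³)`. At a one-hot `W` every
intermediate is an exact dyadic rational, so `F` equals the discrete loss
bit for bit — the tests assert `==`, not approximate equality. `F` is
multilinear in the rows of `W` (second derivatives in any single entry
vanish), so a minimum always exists at a vertex, i.e. a single tree.

## Gradient

The gradient of `F` with respect to every free entry of `W` is computed by
hand-written reverse-mode differentiation of the recursion above — forward
snapshots of `E` per insertion step, then adjoint propagation — in `O(n³)`
total, matching central finite differences to relative error below 1e−4.
A numba-compiled kernel fuses the forward and reverse sweeps (the pure-numpy
implementation is retained as a fallback and agrees to machine precision).

## Optimization within an ordering

Free rows are parameterized by unconstrained scores mapped through a
row-wise softmax; descent starts from zero scores, i.e. the uniform
distribution over all ordered trees. The default update rule is an
Adafactor-style scheme: factored second-moment accumulators (row and column
means of the squared gradient), update clipped to unit RMS, and a step size
`lr · max(1, RMS(θ))` with `lr = 1.0`. Two deliberate departures from
textbook settings matter here: the second-moment decay is capped at 0.9 so
the denominator keeps tracking the exponentially shrinking gradients as the
softmax saturates near a vertex (with slow decay the steps collapse and
convergence to tight tolerances crawls), and the parameter-scale factor lets
the score gap grow geometrically in the saturated phase. Plain gradient
descent and Adam are available as alternatives (`optimizer="gd"|"adam"`).
The loop stops when `|ΔF| < tol` (default 1e−10) or after `max_steps`
(default 1000; typical convergence is 150–400 steps).

Because `F` is linear in each row, the best single-row replacement given the
others can be read directly off the gradient: moving row `m` to the one-hot
at column `j` changes `F` by `g_mj − g_m·W_m`. After gradient convergence
the solution is *polished* by greedily applying the best strictly improving
row move (recomputing the gradient after each) until none remains. The
polish is monotone in `F`, terminates at a vertex, and on enumeration checks
(n = 8) lifts the within-ordering optimum attainment to 100%.

## Queue Shuffle and the outer loop

Queue Shuffle relabels a tree breadth-first: a FIFO queue of internal nodes
starts at the root (label 0); processing a node passes its label to one
child — chosen by a fair independent coin — and gives the other the smallest
unused label, enqueueing the inheriting child immediately ahead of its
sibling. Leaf labels form the new ordering, and the label at which each
fresh value was introduced reads off the tree's vector, so the shuffled
ordering always admits the input tree. The deterministic variant used by
`tree_to_vector` replaces the coin by "the child with the lexicographically
smallest leaf-name set inherits".

The full search (`run_gradme`) repeats {descend from uniform → decode by
argmax → rebuild tree → Queue Shuffle the incumbent} from a seeded random
starting ordering, tracking the best decoded tree by discrete loss, and
stops after `patience` (default 10) consecutive shuffles without incumbent
improvement. The incumbent is expressible after every shuffle, so its loss
trace is non-increasing. All coins and permutations draw from one seeded
generator, making runs bit-reproducible. The search is a stochastic
heuristic: any NNI neighbor of the incumbent is expressible under a shuffled
ordering with probability ≥ 1/4, so a strictly improving rearrangement is
missed for 10 consecutive shuffles with probability up to (3/4)^10 ≈ 5.6%.
In practice 95–99% of additive-input runs recover the exact generating
topology; the guarantee is statistical, not per-run, and the optional
neighbor-joining warm start (`start="nj"`) makes the NJ tree the effective
floor for users who want it.

## Rooting

Rooting changes path edge counts, so the rooted BME loss depends on root
placement. `root_scan` evaluates the rooted loss for the root subdividing
each of the `2n−3` edges and returns the minimizer (preorder traversal,
first minimum kept). On ultrametric distances this recovers the generating
root; intuitively the scan pushes the root as far back in time as the
distances allow, pooling information from all taxa, whereas midpoint rooting
uses only the two farthest leaves. With a near-constant root-to-taxon
distance column (`|D_ni − D*| < δ`), the unrooted objective of the tree with
the root taxon attached and the rooted objective of the tree without it
differ by `D*/2 ± δ/2` under the unordered-pair convention (the `Σ 2^(−depth)
= 1` Kraft identity supplies the factor), which is asserted in the tests.

Branch lengths are needed only as plumbing for midpoint rooting and the
clock diagnostic. `balanced_branch_lengths` computes the Pauplin-weighted
estimates from balanced subtree averages `Δ(A,B) = ½[Δ(A₁,B) + Δ(A₂,B)]`:
pendant edge `l_i = ½(Δ_iA + Δ_iB − Δ_AB)`, internal edge
`l = ¼(Δ_AC + Δ_AD + Δ_BC + Δ_BD) − ½(Δ_AB + Δ_CD)`; exact on additive
inputs, with negative estimates floored at zero (flag recorded on the
returned tree). `ultrametricity_cv` is the population standard deviation of
root-to-tip path lengths divided by their mean — 0 for a strict clock,
scale-invariant.

## Distances from alignments

Sites where either sequence is gapped or ambiguous are excluded pair by pair
(the handling is a package choice; complete deletion per pair is the common
default). Closed forms for DNA: JC69 `d = −¾ ln(1 − 4p/3)`; F81 with
`B = 1 − Σπ²`; TN93 with empirical base frequencies, separate purine and
pyrimidine transition terms, all matching ape's `dist.dna` to 10 decimals on
a frozen fixture. Saturated pairs (log argument ≤ 0) raise an error unless a
cap distance is supplied. Pairwise maximum likelihood: GTR+Γ fits five free
exchangeabilities (GT fixed at 1), a shared Γ shape over 4 equal-probability
discrete categories (a standard choice; the count is configurable), and one
branch time per pair, by L-BFGS on the joint log-likelihood of the pairwise
count matrices; LG uses the published fixed exchangeabilities and
frequencies with a bounded one-dimensional search per pair. With a single
pair the Γ shape is confounded with the branch time (the likelihood depends
only on the mixture transition matrix), so the shape stays near its
initialization on rate-homogeneous data; distances remain accurate to the
simulation-consistency tolerances asserted in the tests (±0.02 at t = 0.2
with 1e5 DNA sites; ±0.05 at t = 0.5 with 1e5 LG sites).

## Synthetic data

`random_ultrametric_tree` draws a Kingman-coalescent-style genealogy
(uniform random pair merges, exponential waiting heights) and rescales node
heights so every leaf sits exactly `total_length` (default 1.0) below the
root — the strict-clock regime in which rooted BME inference is well posed,
and deliberately a hard regime for topology search because coalescent trees
carry very short internal edges near the root. `perturb_branch_lengths`
adds `U(0, eps·ℓ̄)` noise per branch (`ℓ̄` the mean branch length, so `eps`
is a relative noise level), floored at 1e−9. `simulate_alignment` evolves
sites independently down the tree under JC69 or LG with exact
matrix-exponential transition probabilities via the symmetric
eigendecomposition of the reversible generator. What this emulates: clock
and near-clock data with homogeneous rates across sites and lineages. What
it does not: site-rate heterogeneity, clade-specific rate shifts,
alignment error, or indels — so passing tests demonstrate correctness of
the machinery and consistency on clean signals, not robustness to those
real-data phenomena.

Robinson–Foulds distances count bipartitions (default) or clades
(`rooted=True`) present in exactly one tree, normalized by `2(n−3)` or
`2(n−2)` respectively; cross-checked against dendropy. Neighbor joining is
implemented with the standard Q-criterion and a deterministic
smallest-index tie-break, cross-checked against dendropy's NJ.

## Problem sizes and numerical conventions

The test suite exercises enumeration oracles up to n = 7 ((n−1)! = 720
trees), exact point-mass identities up to n = 20, recovery experiments at
n ∈ {8, 12, 16, 20} with 20 replicates each, and rooting experiments at
n = 10 across three noise levels — sizes chosen so the full suite runs in a
few minutes on one CPU while still covering the asymptotically relevant
behavior. Ties everywhere break toward the smallest index (argmax decode,
NJ agglomeration, root scan). Degenerate inputs fail loudly: vectors shorter
than 2, non-binary trees, asymmetric or negative distance matrices, zero
comparable sites in an alignment pair, all-zero branch lengths for midpoint
rooting, zero mean depth for the clock diagnostic.

## Limitations

A gradient evaluation is `O(n³)` and a full run `O(k·l·n³)` for `k` steps
and `l` shuffles, comfortable to a few hundred taxa in this implementation
but not tens of thousands. The outer search carries the stochastic failure
mode quantified above. Rooted inference is meaningful only for data that are
at least approximately clock-like; on strongly non-clock data the root is
drawn toward fast-evolving lineages and only the unrooted topology should
be trusted. Branch lengths are estimated only by the balanced least-squares
plumbing, not jointly with the topology.
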