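# gradme

Continuous phylogenetic inference under balanced minimum evolution (BME), for
rooted and unrooted trees.

Distance methods score a topology `T` on `n` taxa by the BME length

```
L(T) = Σ_{i<j} D_ij · 2^(−e_ij)
```

where `D_ij` is the estimated evolutionary distance between taxa `i` and `j`
and `e_ij` the number of edges on the path between them. Minimizing `L` is
statistically consistent — on exact additive distances the minimizer is the
generating tree — but the space of `(2n−3)!!` topologies makes the discrete
search hard. This package implements a continuous route: topologies are
encoded as *ordered integer vectors* `v` (`v_0 = v_1 = 0`,
`v_m ∈ {0..m−1}`; leaf `m` attaches to the pendant edge labeled `v_m`), a
row-stochastic lower-triangular matrix `W` with `W_mj = P(v_m = j)` describes
a distribution over all `(n−1)!` ordered trees, and the expected loss

```
F(W) = E[ L(T(v)) ] = Σ_{i<j} D_ij · E[2^(−e_ij)]
```

is evaluated exactly in `O(n³)` by a recursion over leaf insertions and
minimized by gradient descent (`F` is multilinear in the rows of `W`, so an
optimum always sits at a single tree). Because one taxon labeling reaches
only `(n−1)!` of all topologies, the search alternates descent with *Queue
Shuffle*: a randomized breadth-first relabeling of the incumbent tree that
always keeps the incumbent expressible while re-randomizing which neighboring
topologies are, admitting each NNI neighbor with probability at least 1/4.
The same machinery supports rooted inference (path lengths counted through
the root) and a rooted-loss scan that places the root of clock-like trees;
midpoint rooting and an ultrametricity score (coefficient of variation of
root-to-tip lengths) are included for comparison.

The package is aimed at people who work with distance matrices or
alignments and want BME topology search, root placement for near-ultrametric
data, or the ordered-vector tree encoding itself (sampling, enumeration,
combinatorics) as a library.

## Worked example

```python
import gradme as g
from gradme.simulate import nj_loss_tree

tree = g.random_ultrametric_tree(15, seed=42)       # ground truth
D = g.additive_distances(tree)                      # exact distances
res = g.run_gradme(D.values, g.OptimizerConfig(mode="unrooted", seed=1),
                   taxon_names=D.names)
nj_tree, nj_loss = nj_loss_tree(D)
print(res.loss, nj_loss, g.rf_distance(res.tree, tree))
```

prints (see `examples/03_infer_from_distances.py`):

```
search finished after 24 shuffles
discrete BME loss: 2.333537 (neighbor joining: 2.333537)
RF distance to the generating tree: 0
```

The loss is the BME length of the returned unrooted topology; Robinson–Foulds
distance 0 means the additive input was recovered exactly, and the loss ties
neighbor joining, which is also exact on additive data. The `examples/`
directory holds one short script per capability (vector encoding, the
continuous objective, inference, rooting, alignment distances); each prints
the numbers it computes and says what they mean. A thin command-line
interface (`gradme dist|infer|root|compare|simulate|demo-onestep`) wraps the
same functions for shell use.

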