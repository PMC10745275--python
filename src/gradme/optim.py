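"""Gradient-descent tree search on the relaxed BME objective.

Within one taxon ordering the free rows of W are parameterized by
unconstrained scores mapped through a row-wise softmax and descended with a
first-order update rule (a factored adaptive scheme by default) until the
objective change falls below tolerance. The column-wise argmax of the
converged W is decoded to a single tree; Queue Shuffle then proposes a new
ordering that still admits the incumbent, and the loop repeats until the
incumbent has not improved for ``patience`` consecutive shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._tree import Tree
from . import bme
from .phylo2vec import TaxonOrdering, build_tree
from .shuffle import queue_shuffle

__all__ = ["OptimizerConfig", "GradMEResult", "optimize_within_ordering", "argmax_vector", "run_gradme"]


@dataclass
class OptimizerConfig:
    """Settings for the relaxed-BME search.

    ``tol`` is the absolute change in F(W) below which the inner gradient
    descent stops (the W matrix is optimized to 1e-10 by default);
    ``patience`` is the number of consecutive shuffles without improvement of
    the incumbent before the outer loop terminates.
    """

    mode: str = "unrooted"
    optimizer: str = "adafactor"  # adafactor | adam | gd
    learning_rate: float = 1.0
    tol: float = 1e-10
    max_steps: int = 1000
    patience: int = 10
    max_shuffles: int = 200
    start: str = "random"  # random | nj ordering initialization
    seed: Optional[int] = None

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.mode not in ("rooted", "unrooted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.optimizer not in ("adafactor", "adam", "gd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class GradMEResult:
    tree: Tree
    loss: float
    ordering: TaxonOrdering
    vector: np.ndarray
    trace: list = field(default_factory=list)  # (shuffle index, incumbent loss)
    n_shuffles: int = 0
    continuous_loss: float = float("nan")


class _Update:
    """First-order update rules on the masked score matrix."""

    def __init__(self, kind: str, lr: float, n: int):
        self.kind = kind
        self.lr = lr
        self.t = 0
        if kind == "adam":
            self.m = np.zeros((n, n))
            self.v = np.zeros((n, n))
        elif kind == "adafactor":
            self.r = np.zeros(n)  # row accumulator of squared grads
            self.c = np.zeros(n)  # column accumulator

    def step(self, theta: np.ndarray, g: np.ndarray) -> np.ndarray:
        self.t += 1
        lr = self.lr
        if self.kind == "gd":
            return theta - lr * g
        if self.kind == "adam":
            b1, b2, eps = 0.9, 0.999, 1e-8
            self.m = b1 * self.m + (1 - b1) * g
            self.v = b2 * self.v + (1 - b2) * g * g
            mhat = self.m / (1 - b1**self.t)
            vhat = self.v / (1 - b2**self.t)
            return theta - lr * mhat / (np.sqrt(vhat) + eps)
        # adafactor-like: factored second moment, no momentum, and the
        # parameter-scale step size that accelerates softmax saturation;
        # the decay cap keeps the denominator tracking the fast-shrinking
        # gradients near a vertex, where convergence would otherwise crawl
        b2, eps = min(1.0 - self.t ** (-0.8), 0.9), 1e-30
        g2 = g * g + eps
        self.r = b2 * self.r + (1 - b2) * g2.mean(axis=1)
        self.c = b2 * self.c + (1 - b2) * g2.mean(axis=0)
        denom = np.sqrt(np.outer(self.r, self.c) / (self.r.mean() + eps)) + eps
        update = g / denom
        rms = np.sqrt(np.mean(update * update)) + eps
        update /= max(1.0, rms)
        scale = max(1.0, np.sqrt(np.mean(theta * theta)))
        return theta - lr * scale * update


def optimize_within_ordering(
    D: np.ndarray,
    ordering: TaxonOrdering,
    cfg: OptimizerConfig,
    name_row: Optional[dict] = None,
) -> tuple[np.ndarray, float]:
    """Descend F(W) from the uniform W at a fixed ordering.

    ``D`` is indexed by taxon (row i = ordering.taxon_names[i]); internally it
    is permuted so that index a corresponds to processing label a. Returns the
    converged W (label-indexed) and its objective value.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    Dl = _relabel_distances(D, ordering, name_row)
    theta = np.zeros((n, n))
    upd = _Update(cfg.optimizer, cfg.learning_rate, n)
    W = bme.w_from_logits(theta)
    gW, f_prev = bme.grad_expected_bme(Dl, W, mode=cfg.mode, check=False, return_value=True)
    for _ in range(cfg.max_steps):
        if not np.all(np.isfinite(gW)):
            raise FloatingPointError("non-finite gradient in relaxed BME descent")
        g = bme.grad_logits(theta, gW)
        theta = upd.step(theta, g)
        W = bme.w_from_logits(theta)
        gW, f = bme.grad_expected_bme(Dl, W, mode=cfg.mode, check=False, return_value=True)
        if not np.isfinite(f):
            raise FloatingPointError("non-finite objective in relaxed BME descent")
        if abs(f_prev - f) < cfg.tol:
            f_prev = f
            break
        f_prev = f
    W, f_prev = _polish_to_vertex(Dl, W, cfg.mode)
    return W, float(f_prev)


def _polish_to_vertex(Dl: np.ndarray, W: np.ndarray, mode: str) -> tuple[np.ndarray, float]:
    """Monotone coordinate descent to a vertex of the W polytope.

    F is linear in each row of W, so the objective change from moving row m to
    the one-hot at column j is g[m, j] - g[m] . W[m] with g the gradient.
    Greedily applying the best strictly-improving row move (recomputing the
    gradient after each) terminates at a single tree that no single-row change
    improves; it can only lower F below the gradient-descent endpoint.
    """
    n = W.shape[0]
    W = W.copy()
    while True:
        gW, f = bme.grad_expected_bme(Dl, W, mode=mode, check=False, return_value=True)
        best_delta, best_move = -1e-14, None
        for m in range(2, n):
            j = int(np.argmin(gW[m, :m]))
            delta = gW[m, j] - float(gW[m, :m] @ W[m, :m])
            if delta < best_delta:
                best_delta, best_move = delta, (m, j)
        if best_move is None:
            return W, float(f)
        m, j = best_move
        W[m, :] = 0.0
        W[m, j] = 1.0


def argmax_vector(W: np.ndarray) -> np.ndarray:
    """Decode W to a single ordered vector by row-wise argmax (ties -> smallest)."""
    n = W.shape[0]
    v = np.zeros(n, dtype=int)
    for m in range(2, n):
        v[m] = int(np.argmax(W[m, :m]))
    return v


def _relabel_distances(
    D: np.ndarray, ordering: TaxonOrdering, name_row: Optional[dict] = None
) -> np.ndarray:
    """Permute D (taxon-indexed) so that index a corresponds to label a.

    ``name_row`` maps taxon name -> row of D; positional correspondence with
    ``ordering.taxon_names`` is assumed when it is omitted.
    """
    inv = ordering.inverse()
    if name_row is None:
        rows = np.array(inv)
    else:
        rows = np.array([name_row[ordering.taxon_names[i]] for i in inv])
    return D[np.ix_(rows, rows)]


def _discrete_loss(
    D: np.ndarray, v: np.ndarray, ordering: TaxonOrdering, mode: str, name_row: Optional[dict] = None
) -> float:
    Dl = _relabel_distances(D, ordering, name_row)
    e = bme.path_lengths_from_vector(v, mode=mode)
    return bme.bme_loss(Dl, e)


def run_gradme(
    D: np.ndarray,
    cfg: Optional[OptimizerConfig] = None,
    taxon_names=None,
) -> GradMEResult:
    """Full search: gradient descent within an ordering + Queue Shuffle moves.

    The incumbent is the best argmax-decoded tree by discrete BME loss; it is
    expressible after every shuffle, so the incumbent loss never increases.
    In unrooted mode the returned tree is the incumbent with its root
    suppressed (several rooted vectors decode to the same unrooted tree).
    """
    cfg = cfg or OptimizerConfig()
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if taxon_names is None:
        taxon_names = [str(i) for i in range(n)]
    rng = np.random.default_rng(cfg.seed)
    name_row = {nm: i for i, nm in enumerate(taxon_names)}

    if cfg.start == "nj":
        from .simulate import neighbor_joining

        nj = neighbor_joining(D, taxon_names=taxon_names)
        start_tree = nj.root_on_edge(nj.edges()[0])
        ordering, _ = queue_shuffle(start_tree, rng)
    else:
        sigma = tuple(int(x) for x in rng.permutation(n))
        ordering = TaxonOrdering(tuple(taxon_names), sigma)

    best_loss = np.inf
    best_v = None
    best_ordering = None
    best_cont = np.nan
    trace: list[tuple[int, float]] = []
    stall = 0
    shuffle_idx = 0
    while shuffle_idx < cfg.max_shuffles:
        W, f_cont = optimize_within_ordering(D, ordering, cfg, name_row)
        v = argmax_vector(W)
        loss = _discrete_loss(D, v, ordering, cfg.mode, name_row)
        if loss < best_loss - 1e-15:
            best_loss, best_v, best_ordering, best_cont = loss, v, ordering, f_cont
            stall = 0
        else:
            stall += 1
        trace.append((shuffle_idx, float(best_loss)))
        shuffle_idx += 1
        if stall >= cfg.patience:
            break
        incumbent = build_tree(best_v, best_ordering)
        ordering, _ = queue_shuffle(incumbent, rng)

    tree = build_tree(best_v, best_ordering)
    if cfg.mode == "unrooted":
        tree = tree.unroot()
    return GradMEResult(
        tree=tree,
        loss=float(best_loss),
        ordering=best_ordering,
        vector=best_v,
        trace=trace,
        n_shuffles=shuffle_idx,
        continuous_loss=best_cont,
    )
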