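"""Pairwise evolutionary distance estimation from multiple sequence alignments.

Implements the uncorrected p-distance, the closed-form JC69 / F81 / TN93
corrections for DNA, and pairwise maximum-likelihood distances under GTR+Gamma
(DNA; exchangeabilities, shape and all branch times fitted jointly) or the
fixed LG model (amino acids). Sites where either sequence is ambiguous or
gapped are excluded pair by pair (complete deletion per pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from . import models

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "SaturationError",
    "p_distance",
    "closed_form_distance",
    "ml_pairwise_distance",
]


class SaturationError(ValueError):
    """Raised when a distance correction is undefined (saturated pair)."""


@dataclass
class Alignment:
    """Equal-length named sequences over a DNA or amino-acid alphabet."""

    names: list
    sequences: list
    alphabet: str = "dna"  # "dna" | "protein"

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in number")
        if len(set(self.names)) != len(self.names):
            dup = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate sequence names: {dup}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def states(self) -> str:
        return models.DNA_ALPHABET if self.alphabet == "dna" else models.AA_ALPHABET

    def encoded(self) -> np.ndarray:
        """Integer matrix; unambiguous states 0..K-1, everything else -1."""
        lookup = np.full(256, -1, dtype=np.int8)
        for i, ch in enumerate(self.states):
            lookup[ord(ch)] = i
        out = np.empty((self.n_sequences, self.n_sites), dtype=np.int8)
        for r, seq in enumerate(self.sequences):
            out[r] = lookup[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        return out


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with taxon names."""

    names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match names")
        if len(set(self.names)) != n:
            raise ValueError("duplicate taxon names")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.names)


def _pair_counts(enc: np.ndarray, i: int, j: int, k: int) -> np.ndarray:
    """K x K matrix of joint state counts over pairwise-complete sites."""
    a, b = enc[i], enc[j]
    ok = (a >= 0) & (b >= 0)
    if not np.any(ok):
        raise ValueError(f"sequences {i} and {j} share no unambiguous sites")
    return np.bincount((a[ok].astype(int) * k + b[ok]), minlength=k * k).reshape(k, k).astype(float)


def p_distance(aln: Alignment) -> DistanceMatrix:
    """Proportion of differing sites among pairwise-unambiguous sites."""
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    enc = aln.encoded()
    n = aln.n_sequences
    out = np.zeros((n, n))
    bad = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[i], enc[j]
            ok = (a >= 0) & (b >= 0)
            tot = int(ok.sum())
            if tot == 0:
                bad.append((aln.names[i], aln.names[j]))
                continue
            out[i, j] = out[j, i] = float(np.sum(a[ok] != b[ok])) / tot
    if bad:
        raise ValueError(f"pairs with no comparable sites: {bad}")
    return DistanceMatrix(list(aln.names), out)


def _empirical_freqs(enc: np.ndarray, k: int) -> np.ndarray:
    counts = np.bincount(enc[enc >= 0].astype(int), minlength=k).astype(float)
    if np.any(counts == 0):
        counts += 1.0  # avoid zero frequencies on tiny alignments
    return counts / counts.sum()


def _correct(arg: float, pair: tuple, cap: Optional[float]) -> Optional[float]:
    """Validate a log argument; None means 'use the cap'."""
    if arg <= 0:
        if cap is None:
            raise SaturationError(
                f"distance undefined for pair {pair}: correction saturated"
            )
        return cap
    return None


def closed_form_distance(
    aln: Alignment, model: str = "JC69", cap: Optional[float] = None
) -> DistanceMatrix:
    """JC69, F81 or TN93 distances for DNA alignments.

    Saturated pairs raise :class:`SaturationError` unless ``cap`` supplies a
    maximum distance to substitute.
    """
    model = model.upper()
    if model not in ("JC69", "F81", "TN93"):
        raise ValueError(f"unknown closed-form model {model!r}")
    if aln.alphabet != "dna":
        raise ValueError("closed-form corrections are defined for DNA")
    enc = aln.encoded()
    n = aln.n_sequences
    pi = _empirical_freqs(enc, 4)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = (aln.names[i], aln.names[j])
            N = _pair_counts(enc, i, j, 4)
            tot = N.sum()
            p = (tot - np.trace(N)) / tot
            if model == "JC69":
                arg = 1.0 - 4.0 * p / 3.0
                capped = _correct(arg, pair, cap)
                d = capped if capped is not None else -0.75 * np.log(arg)
            elif model == "F81":
                B = 1.0 - float(np.sum(pi**2))
                arg = 1.0 - p / B
                capped = _correct(arg, pair, cap)
                d = capped if capped is not None else -B * np.log(arg)
            else:
                d = _tn93(N, pi, pair, cap)
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(aln.names), out)


def _tn93(N: np.ndarray, pi: np.ndarray, pair: tuple, cap: Optional[float]) -> float:
    # alphabet order ACGT: purines A(0), G(2); pyrimidines C(1), T(3)
    tot = N.sum()
    S = N + N.T
    p1 = S[0, 2] / tot  # A<->G transitions
    p2 = S[1, 3] / tot  # C<->T transitions
    q = (S[0, 1] + S[0, 3] + S[1, 2] + S[2, 3]) / tot  # transversions
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    k1 = 2.0 * piA * piG / piR
    k2 = 2.0 * piT * piC / piY
    k3 = 2.0 * (piR * piY - piA * piG * piY / piR - piT * piC * piR / piY)
    args = (1.0 - p1 / k1 - q / (2.0 * piR), 1.0 - p2 / k2 - q / (2.0 * piY), 1.0 - q / (2.0 * piR * piY))
    for arg in args:
        capped = _correct(arg, pair, cap)
        if capped is not None:
            return capped
    return float(-k1 * np.log(args[0]) - k2 * np.log(args[1]) - k3 * np.log(args[2]))


# --------------------------------------------------------------------- #
# pairwise maximum likelihood
# --------------------------------------------------------------------- #
@dataclass
class ModelSpec:
    """Fitted substitution model description."""

    name: str
    frequencies: np.ndarray
    exchangeabilities: Optional[np.ndarray] = None  # GTR upper triangle
    gamma_shape: Optional[float] = None
    converged: bool = True
    extra: dict = field(default_factory=dict)


def _gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability discrete-Gamma categories."""
    quantiles = (np.arange(ncat) + 0.5) / ncat
    rates = stats.gamma.ppf(quantiles, a=alpha, scale=1.0 / alpha)
    return rates / rates.mean()


def _pair_loglik(model: models.SpectralModel, counts: np.ndarray, t: float, rates: np.ndarray) -> float:
    mix = np.zeros_like(counts)
    for r in rates:
        mix += model.transition_matrix(t * r)
    mix /= len(rates)
    joint = model.freqs[:, None] * mix
    return float(np.sum(counts * np.log(joint)))


def ml_pairwise_distance(
    aln: Alignment,
    model: str = "GTR+G",
    n_categories: int = 4,
    max_iter: int = 500,
) -> tuple[DistanceMatrix, ModelSpec]:
    """Distances maximizing the pairwise likelihood.

    GTR+G fits 5 free exchangeabilities (GT fixed at 1), a Gamma shape shared
    across pairs (``n_categories`` equal-probability categories) and one branch
    time per pair, jointly by quasi-Newton ascent from the counts. LG uses the
    published fixed exchangeabilities and frequencies, leaving one branch time
    per pair. Non-convergence warns and returns the best values found.
    """
    name = model.upper().replace("GAMMA", "G")
    enc = aln.encoded()
    n = aln.n_sequences
    if n < 2:
        raise ValueError("need at least 2 sequences")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    if name == "LG":
        if aln.alphabet != "protein":
            raise ValueError("LG is an amino-acid model")
        mdl = models.lg_model()
        counts = {p: _pair_counts(enc, *p, 20) for p in pairs}
        out = np.zeros((n, n))
        rates = np.ones(1)
        for (i, j) in pairs:
            N = counts[(i, j)]
            if N.sum() == np.trace(N):
                continue  # identical sequences -> distance 0
            res = optimize.minimize_scalar(
                lambda t: -_pair_loglik(mdl, N, t, rates),
                bounds=(1e-8, 50.0),
                method="bounded",
            )
            out[i, j] = out[j, i] = float(res.x)
        spec = ModelSpec("LG", mdl.freqs)
        return DistanceMatrix(list(aln.names), out), spec

    if name not in ("GTR+G", "GTR"):
        raise ValueError(f"unknown ML model {model!r}")
    if aln.alphabet != "dna":
        raise ValueError("GTR is a DNA model")
    pi = _empirical_freqs(enc, 4)
    counts = {p: _pair_counts(enc, *p, 4) for p in pairs}
    use_gamma = name == "GTR+G"

    # parameters: log exch (5, GT ref), log alpha (if gamma), log t per pair
    t0 = []
    for p in pairs:
        N = counts[p]
        pdist = (N.sum() - np.trace(N)) / N.sum()
        t0.append(max(pdist, 1e-4))
    n_exch = 5
    x0 = np.concatenate([np.zeros(n_exch), [0.0] if use_gamma else [], np.log(t0)])

    def unpack(x):
        exch = np.concatenate([np.exp(x[:n_exch]), [1.0]])
        k = n_exch
        alpha = None
        if use_gamma:
            alpha = float(np.exp(x[k]))
            k += 1
        ts = np.exp(x[k:])
        return exch, alpha, ts

    def negloglik(x):
        exch, alpha, ts = unpack(x)
        mdl = models.gtr_model(exch, pi)
        rates = _gamma_rates(alpha, n_categories) if use_gamma else np.ones(1)
        ll = 0.0
        for (pair, t) in zip(pairs, ts):
            ll += _pair_loglik(mdl, counts[pair], t, rates)
        return -ll

    res = optimize.minimize(negloglik, x0, method="L-BFGS-B", options={"maxiter": max_iter})
    if not res.success:
        import warnings

        warnings.warn(f"pairwise ML did not converge: {res.message}", RuntimeWarning)
    exch, alpha, ts = unpack(res.x)
    out = np.zeros((n, n))
    for (i, j), t in zip(pairs, ts):
        N = counts[(i, j)]
        d = 0.0 if N.sum() == np.trace(N) else float(t)
        out[i, j] = out[j, i] = d
    spec = ModelSpec(
        "GTR+G" if use_gamma else "GTR",
        pi,
        exchangeabilities=exch,
        gamma_shape=alpha,
        converged=bool(res.success),
    )
    return DistanceMatrix(list(aln.names), out), spec
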